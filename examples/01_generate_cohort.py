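"""Generate a synthetic hypertension EHR cohort and inspect its structure.

The generator emits raw event streams (measurements, prescriptions,
demographics) plus a counterfactual truth table: for every evaluable
90-day period, the next-period mean SBP the patient *would* have had under
each of the 7 monotherapy classes and under continuing their current
regimen.  Models never see the truth table; the evaluation harness uses it
to score policies without estimation bias.
"""

import bprx

cfg = bprx.GeneratorConfig(n_patients=100, seed=1)
cohort = bprx.generate_cohort(cfg)

print(f"patients:        {cfg.n_patients}")
print(f"measurements:    {len(cohort.measurements)} rows "
      f"({cohort.measurements['kind'].nunique()} kinds)")
print(f"prescriptions:   {len(cohort.prescriptions)} intervals")
print(f"truth entries:   {len(cohort.truth)} (patient, period, option) rows")

# which drug class is truth-optimal varies across patients — the
# heterogeneity the personalized model is supposed to exploit
mono = cohort.truth[cohort.truth.option != bprx.CURRENT_OPTION]
best = mono.loc[mono.groupby(["patient_id", "period_index"])["future_sbp"].idxmin()]
print("\ntruth-optimal class shares (%):")
print((best["option"].value_counts(normalize=True) * 100).round(1).to_string())

# event tables round-trip through plain CSVs
paths = cohort.to_csv("scratch/example_cohort")
print("\nwrote:", ", ".join(str(p) for p in paths.values()))
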