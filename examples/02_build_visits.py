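"""Turn raw event streams into the visit-level modeling table.

Patients pass inclusion screening (hypertension criteria, two SBP readings
within 180 days, at least one antihypertensive), their timeline is cut into
90-day periods anchored at the first SBP record, measurements are averaged
per period, and the outcome — mean SBP one period ahead — is attached.
"""

import bprx
from bprx.cohort import modeling_table, select_cohort, split_by_patient

cohort = bprx.generate_cohort(bprx.GeneratorConfig(n_patients=150, seed=2))

included = select_cohort(
    cohort.measurements, cohort.prescriptions, cohort.demographics
)
print(f"patients passing inclusion: {len(included)} / 150")

visits = bprx.build_visit_table(cohort)
usable = modeling_table(visits)
print(f"visits: {len(visits)}, with valid future outcome: {len(usable)}")
print(f"combination-regimen visits: {(usable['n_active_classes'] >= 2).sum()}")
print(f"untreated visits: {(usable['regimen'] == '').sum()}")

train, val, test = split_by_patient(visits, fractions=(0.8, 0.1, 0.1), seed=0)
print(f"patient-disjoint split: {train.patient_id.nunique()} / "
      f"{val.patient_id.nunique()} / {test.patient_id.nunique()} patients")

schema = bprx.default_schema().fit(modeling_table(train))
X = schema.transform(modeling_table(test))
print(f"feature matrix (test): {X.shape} — standardized with train statistics only")
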