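"""Turn counterfactual panels into rule-constrained prescriptions.

Hard contraindication rules zero out unsafe options (bradycardia excludes
beta-blockers, hyperkalemia excludes RAAS agents and MRAs, renal impairment
excludes ACEi/ARB/thiazide); advisory rules boost guideline-preferred
options.  A softmax over the surviving menu converts predicted SBP into
recommendation probabilities, and a switch threshold keeps the current
regimen unless the predicted improvement is material.
"""

from bprx.neighbors import CounterfactualPanel
from bprx.policy import PolicyConfig, decide
from bprx.synthetic import CURRENT_OPTION

panel = CounterfactualPanel(
    visit_id=42,
    regimen="ACEi+Thiazide",
    predictions={
        "CCB": 139.2, "Thiazide": 137.8, "ARB": 141.0, "ACEi": 140.5,
        "BetaBlocker": 138.9, "LoopDiuretic": 143.1, "MRA": 142.4,
        CURRENT_OPTION: 141.7,
    },
)
visit = {"pulse": 55.0, "potassium": 4.7, "creatinine": 1.1,
         "diabetes": 1, "systolic_hf": 0}

rec = decide(panel, visit, PolicyConfig(mode="randomized", xi=0.5, delta=2.0, seed=7))

print(f"visit {rec.visit_id} on {panel.regimen}; labs: pulse 55, K 4.7")
print("\nexclusions (hard rules):")
for opt, rules in sorted(rec.excluded.items()):
    print(f"  {opt:<13} {', '.join(rules)}")
print("\nrecommendation probabilities:")
for opt, p in sorted(rec.probabilities.items(), key=lambda kv: -kv[1]):
    print(f"  {opt:<13} {p:6.3f}")
print(f"\nchosen: {rec.chosen} (kept current: {rec.kept_current})")
print("\nBradycardia removed the beta-blocker and K > 4.5 removed ACEi/ARB —")
print("including the 'current' option, since the current regimen contains")
print("ACEi.  Probabilities over the remaining menu sum to one.")
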