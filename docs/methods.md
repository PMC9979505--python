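# Methods

This note records the modeling assumptions, default parameters, numerical
choices and known limitations behind `bprx`.  It is the package's own
account of its science; every empirical statement here is computed by the
test suite or by `scripts/acceptance.py`.

## Problem setting

The unit of analysis is the *visit*: a 90-day review period anchored at a
patient's first recorded systolic blood pressure (SBP), not a physical
encounter.  The outcome y of a visit starting at day s is the mean SBP over
[s + 90, s + 180) — the next period — and is missing (the visit is dropped
from modeling) when no SBP was charted in that window.  Period bins are
half-open [s, s + 90), so a measurement exactly at s + 90 belongs to the
next visit; this prevents double counting and is pinned by a unit test.
The outcome offset is a parameter (`attach_outcomes(offset=...)`) because
"the next visit" can reasonably be referenced from the period start or the
period end; the default, 90 days from the period start, makes the outcome
window coincide with the following visit.

Observed outcomes exist only under the drug actually given.  All other
menu options require counterfactual prediction, and the prescribing in the
data is confounded: clinicians condition on the same covariates that drive
the outcome.  The design below does not attempt formal deconfounding; it
follows the pragmatic matched-cohort logic of regression-informed nearest
neighbors, and the synthetic evaluation quantifies how much value that
recovers under a known confounded behavior policy.

## Per-class outcome regressions

One regression of y on the standardized visit features is fitted per drug
class, on every training visit whose regimen *includes* that class
(combination regimens contribute a row to each constituent class), plus an
eighth model on untreated visits so the continue-current option is defined
for drug-naive patients.

* **OLS** — least squares via the normal equations / lstsq, with an
  explicit rank check; rank-deficient designs either raise an error naming
  the collinear columns (from a pivoted QR) or fall back to a 1e-8 ridge.
* **LASSO** — MSE + λ‖β‖₁ through scikit-learn (its `alpha` is λ/2 under
  the 1/(2n) loss scaling); λ defaults to 0.01 or is chosen on the
  validation set by MSE over a log grid.
* **CART** — scikit-learn's variance-reduction tree.  Trees have no
  coefficient vector, so the normalized impurity importances stand in as
  non-negative metric weights; in the algorithm comparison CART (like
  LASSO) predicts directly rather than through the neighbor metric.
* **DRLR** — the robust member: mean absolute loss plus ε times the dual
  norm of (−β, 1), the regularized equivalent of absolute-loss regression
  hedged over a Wasserstein ball of radius ε.  The ground metric on (x, y)
  space is ℓ₂ by default (dual norm √(1 + ‖β‖²)); ℓ₁ and ℓ∞ are options.

DRLR solver: polyhedral cases (ε = 0, or ℓ₁/ℓ∞ ground metrics) are solved
exactly as linear programs with HiGHS.  The ℓ₂ case uses pseudo-Huber
smoothing of |r| with a continuation schedule μ = 10 → 1e-6 and L-BFGS at
each stage; the smoothing gap is bounded by μ, so the final objective is
within ~1e-6 of the nonsmooth optimum — verified against an independently
formulated LP (relative gap ≤ 1e-6 on 20 random problems) and against
statsmodels' IRLS median regression.  The intercept is never penalized and
never enters the distance metric (it is constant across patients).

Default ε = 0.01.  The ambiguity radius trades robustness against bias;
0.01 keeps coefficient shrinkage negligible on clean data while retaining
the absolute-loss resistance to the ±50 mmHg entry errors the generator
produces.  A validation-grid search over {0, 1e-3, …, 0.3} is available
(`tune=True`) but the pipeline defaults avoid it for speed.

## Counterfactual K-nearest neighbors

Distance between standardized feature vectors: ‖x − z‖_β =
√(Σ (xᵢ − zᵢ)² βᵢ²), with β the class model's coefficients.  Features are
z-scored with training-set statistics (frozen in the schema, never refit)
so the βᵢ² weights are comparable across units.  The prediction for class
m is the unweighted mean outcome of the K closest training visits on m.

Numerical and procedural choices:

* Search is exact (full scan) — pools are desk-scale and exactness is part
  of the contract, confirmed against a per-pair oracle.
* Distance ties break by ascending visit id: deterministic and
  reproducible.
* K defaults to 50; a grid {10, 25, 50, 100} can be tuned on validation
  data.  Pools smaller than K use all members and set a `short_pool` flag.
* A query's own patient is never admitted to its neighborhood, extending
  patient-disjoint split hygiene to in-set predictions.
* The current-regimen option of a monotherapy visit coincides with that
  class's option (menu size 7); combinations and untreated regimens get a
  distinct "current" option (menu size 8).  A combination's metric weights
  are the mean of the constituent classes' coefficient vectors, and its
  pool is the set-equality regimen pool, falling back to the union of
  constituent pools (flagged) when fewer than K exact matches exist.

## Prescription policy

Hard rules remove contraindicated options, including the current-regimen
option when the active regimen contains a contraindicated class; if every
option is excluded the policy falls back to the current regimen with a
warning status.  Missing labs leave a rule untriggered and are reported as
unevaluable — conservative and transparent.  Advisory rules multiply the
softmax weight of preferred options by `soft_preference_weight`
(default 1.5; 1 disables), an annotation-strength encoding of "should
likely be on".

The randomized policy draws option m with probability ∝ w_m e^{−ξ ŷ_m},
computed with a max-shift for stability; ξ defaults to 0.5 /mmHg, and
`tune_xi` picks the smallest grid value whose expected predicted SBP is
within 1 mmHg of the deterministic argmin's, preserving exploration up to
a performance constraint.  The switch threshold δ defaults to 0 mmHg — no
published constant exists for it — and the evaluation can be run at any
δ; probabilities are unaffected, only the keep-current decision moves.

## Synthetic cohort: what it emulates, and what it does not

Per patient: age ~ N(61, 12²), 52% female, race mix dominated by Black
(50%) and White (26%) patients, smoking 28%, diabetes 45%, systolic heart
failure 4%, and rule-triggering labs at configurable per-patient rates
(bradycardia 8%, K⁺ > 4.5 10%, K⁺ > 5 3%, creatinine ≥ 2 5%).  SBP follows
a period-level AR(1): m_{t+1} = ρ m_t + (1 − ρ) setpoint + effect(regimen,
covariates) + noise, ρ = 0.7, setpoint ~ N(150, 12²), noise_sd = 4 mmHg.
Drug effects are linear in standardized age, diabetes, Black race and two
latent traits (volume/salt sensitivity, renin-angiotensin activity), with
base effects of −8 to −11.5 mmHg chosen so the truth-optimal class varies
across patients in clinically plausible directions (diuretics favour
volume-sensitive and Black patients, RAAS agents diabetic and high-renin
patients).  The latent traits are deliberately unobservable: part of the
heterogeneity is irreducible, as in real data.  Prescribing follows a
logistic guideline-flavored behavior policy (diabetics more often on
ACEi/ARB, bradycardics rarely on beta-blockers, initiation probability
rising with SBP), so assignments are confounded; 25% of treated visits are
two-class combinations with sub-additive (×0.8) combined effects.
Measurements are charted at 0.01 mmHg resolution, 1–3 SBP readings per
period, labs once per period, 5% of rows missing completely at random;
entry errors shift a configured fraction of SBP rows by ±50 mmHg.  The
truth table stores the noise-free transition target under every menu
option; contamination never touches it.

The generator does *not* emulate: informative missingness, within-period
trends, dose titration, adherence, measurement-device bias, ICD-coded
histories, or free text.  Passing tests therefore demonstrate correctness
of the machinery and the claimed statistical orderings under linear
heterogeneous effects with confounded assignment — not clinical validity
on real EHR data, whose access restrictions are the reason the generator
exists.

## Evaluation protocol and problem sizes

The harness refits everything per split (patients partitioned 80/10/10 by
largest-remainder allocation), builds panels and recommendations, and
reports mean ± SD reductions across splits for LASSO, CART, OLS+KNN and
DRLR+KNN under deterministic and randomized modes, plus the
current-regimen and standard-of-care references.  On synthetic cohorts a
truth-based reduction is reported separately from the model-estimated one
so prediction optimism stays visible (model-estimated reductions are
systematically larger — choosing the argmin of noisy predictions selects
favorable noise; the truth columns are the honest yardstick).

Problem sizes used by the shipped checks: the algorithm-comparison table
runs 5 splits on an 800-patient cohort; the truth-based policy-value check
runs 5 splits on a 2,000-patient cohort with K = 50; the contamination
ordering uses 20 seeds at n = 200, p = 5; seed-level majority properties
run 20 cohorts of 150 patients.  These sizes give stable orderings (the
policy-value check passes 5/5 splits; the contamination check 20/20 seeds
at seed 1) while keeping a full run on one CPU to a few minutes.

## Known limitations

* Counterfactual KNN matches on observables only; unobserved confounding
  biases per-class predictions, and the synthetic latent traits reproduce
  exactly this failure mode in miniature.
* Per-class pools shrink for rare classes (MRA, loop diuretics) and rare
  combinations; short-pool and fallback flags surface this, but
  predictions there are noisier and the policy can over-select them.
* The absolute-loss robustness addresses outcome outliers; gross feature
  corruption is only partially covered by the Wasserstein penalty.
* `percent_improvement` compares magnitudes of signed reductions; it is
  undefined for a zero reference and misleading when the two reductions
  have opposite signs — callers see the raw means alongside every ratio.
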