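"""Synthetic longitudinal EHR generator with known counterfactual ground truth.

Real hypertension-management EHR data are restricted, so every downstream
stage of the pipeline (visit construction, per-class outcome regression,
counterfactual KNN, policy evaluation) is exercised against cohorts generated
here.  The generator emulates the structure of an urban safety-net hospital
population: 90-day review periods anchored at the first systolic blood
pressure (SBP) record, patient-level SBP dynamics drifting toward an
individual setpoint, seven antihypertensive drug classes (plus combinations)
with covariate-dependent heterogeneous effects, labs that trigger clinical
contraindication rules, comorbidity flags, entry-error outliers, and
missing measurements.

Crucially it also emits a *truth table*: for every evaluable (patient,
period) pair, the counterfactual next-period mean SBP under each of the
seven monotherapies and under continuation of the current regimen.  That
table is the oracle the evaluation harness is validated against; no model
ever sees it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

DRUG_CLASSES = (
    "CCB",
    "Thiazide",
    "ARB",
    "ACEi",
    "BetaBlocker",
    "LoopDiuretic",
    "MRA",
)

#: label for the continue-current-prescription menu option
CURRENT_OPTION = "current"
#: regimen string of an untreated period
NO_REGIMEN = ""

# Interaction covariates recognised by the effect matrix, in order:
# standardized age, diabetes flag, Black race flag, and two latent traits
# (volume/salt sensitivity and renin-angiotensin activity) that are *not*
# observable by the models — they create irreducible heterogeneity.
EFFECT_COVARIATES = ("age_z", "diabetes", "black", "trait_volume", "trait_ras")

# Default per-class SBP effects in mmHg (negative = lowering) with
# covariate interactions chosen so the truth-optimal class varies across
# patients: diuretics favour volume-sensitive and Black patients,
# ACEi/ARB favour diabetic and high-renin patients, beta-blockers are
# mid-pack, mirroring broad clinical expectation.
DEFAULT_EFFECT_MATRIX = {
    "CCB":          {"base": -11.0, "age_z": -1.0, "diabetes":  0.0, "black": -2.0, "trait_volume": -2.0, "trait_ras":  1.0},
    "Thiazide":     {"base": -11.5, "age_z":  0.5, "diabetes":  1.0, "black": -2.5, "trait_volume": -3.0, "trait_ras":  1.5},
    "ARB":          {"base": -10.5, "age_z":  0.0, "diabetes": -2.0, "black":  2.0, "trait_volume":  1.5, "trait_ras": -3.0},
    "ACEi":         {"base": -10.8, "age_z":  0.0, "diabetes": -2.5, "black":  2.5, "trait_volume":  1.5, "trait_ras": -3.5},
    "BetaBlocker":  {"base":  -9.0, "age_z": -1.5, "diabetes":  0.5, "black":  1.0, "trait_volume":  0.0, "trait_ras": -1.5},
    "LoopDiuretic": {"base":  -8.0, "age_z":  0.5, "diabetes":  0.0, "black": -1.0, "trait_volume": -2.5, "trait_ras":  0.5},
    "MRA":          {"base":  -8.5, "age_z":  0.0, "diabetes":  0.0, "black": -1.5, "trait_volume": -2.0, "trait_ras": -1.0},
}

DEFAULT_RULE_TRIGGER_FRACTIONS = {
    "low_pulse": 0.08,      # resting pulse < 60
    "k_gt_45": 0.10,        # potassium > 4.5 (mild)
    "k_gt_5": 0.03,         # potassium > 5 (on top of mild)
    "creat_ge_2": 0.05,     # creatinine >= 2
    "diabetes": 0.45,
    "systolic_hf": 0.04,
}

#: sub-additivity of combined drug effects
COMBO_ATTENUATION = 0.8


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic cohort.

    Defaults describe the study conditions the rest of the package is
    evaluated under; they are not meant to be tuned per run.
    """

    n_patients: int = Field(default=500, ge=1)
    horizon_days: int = Field(default=720, ge=180)
    visit_period: int = Field(default=90, ge=1)
    drug_classes: tuple[str, ...] = DRUG_CLASSES
    effect_matrix: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_EFFECT_MATRIX.items()}
    )
    noise_sd: float = Field(default=4.0, ge=0.0)
    outlier_fraction: float = Field(default=0.0, ge=0.0, lt=1.0)
    outlier_magnitude: float = Field(default=50.0, ge=0.0)
    missing_fraction: float = Field(default=0.05, ge=0.0, lt=1.0)
    combo_fraction: float = Field(default=0.25, ge=0.0, lt=1.0)
    rule_trigger_fractions: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_RULE_TRIGGER_FRACTIONS)
    )
    ar_coefficient: float = Field(default=0.7, ge=0.0, le=1.0)
    fixed_regimen: Optional[tuple[str, ...]] = None
    seed: int = 0

    @field_validator("rule_trigger_fractions")
    @classmethod
    def _fractions_in_range(cls, v: dict[str, float]) -> dict[str, float]:
        for key, frac in v.items():
            if not (0.0 <= frac < 1.0):
                raise ValueError(f"rule_trigger_fractions[{key!r}] must be in [0, 1), got {frac}")
        return v

    @model_validator(mode="after")
    def _effect_matrix_rows(self) -> "GeneratorConfig":
        missing = [c for c in self.drug_classes if c not in self.effect_matrix]
        if missing:
            raise ValueError(f"effect_matrix missing rows for drug classes: {missing}")
        if self.fixed_regimen is not None:
            unknown = [c for c in self.fixed_regimen if c not in self.drug_classes]
            if unknown:
                raise ValueError(f"fixed_regimen contains unknown classes: {unknown}")
        return self


@dataclass
class SyntheticCohort:
    """Event streams plus the counterfactual ground truth behind them.

    measurements : rows (patient_id, day, kind, value); kinds are
        sbp, dbp, pulse, potassium, creatinine, spo2 (all numeric).
    prescriptions : rows (patient_id, start_day, end_day, drug_class),
        inclusive day intervals.
    demographics : one row per patient with static covariates and flags.
    truth : rows (patient_id, period_index, option, future_sbp) with one
        row per menu option (7 monotherapies + "current") for every period
        that has a valid outcome window.
    generative_params : effect matrix and the per-patient latent table
        (setpoint, traits) — diagnostics only, never model inputs.
    """

    measurements: pd.DataFrame
    prescriptions: pd.DataFrame
    demographics: pd.DataFrame
    truth: pd.DataFrame
    generative_params: dict
    config: GeneratorConfig

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(
            measurements=self.measurements.copy(),
            prescriptions=self.prescriptions.copy(),
            demographics=self.demographics.copy(),
            truth=self.truth.copy(),
            generative_params=dict(self.generative_params),
            config=self.config,
        )

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("measurements", self.measurements),
            ("prescriptions", self.prescriptions),
            ("demographics", self.demographics),
            ("truth", self.truth),
        ]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths

    def csv_digest(self) -> str:
        """Concatenated CSV text of all four tables (determinism checks)."""
        buf = io.StringIO()
        for df in (self.measurements, self.prescriptions, self.demographics, self.truth):
            df.to_csv(buf, index=False)
        return buf.getvalue()


def _drug_effect(row_effects: dict[str, float], covars: dict[str, float]) -> float:
    e = row_effects["base"]
    for name in EFFECT_COVARIATES:
        e += row_effects.get(name, 0.0) * covars[name]
    return e


def _regimen_effect(regimen: tuple[str, ...], effect_matrix, covars) -> float:
    if not regimen:
        return 0.0
    total = sum(_drug_effect(effect_matrix[c], covars) for c in regimen)
    if len(regimen) > 1:
        total *= COMBO_ATTENUATION
    return total


def _behavior_scores(classes, demo, pulse_base) -> np.ndarray:
    """Guideline-flavored standard-of-care propensities (confounded on purpose)."""
    scores = np.zeros(len(classes))
    for j, c in enumerate(classes):
        s = 0.0
        if c in ("ACEi", "ARB"):
            s += 1.2 * demo["diabetes"]
        if c == "BetaBlocker":
            s += 1.5 * demo["systolic_hf"]
            if pulse_base < 60:
                s -= 3.0
        if c in ("CCB", "Thiazide"):
            s += 0.8 * (demo["race"] == "Black")
        if c in ("LoopDiuretic", "MRA"):
            s -= 1.2  # less common first-line agents
        scores[j] = s
    return scores


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Simulate the event streams and counterfactual truth for one cohort.

    The SBP trajectory of patient *i* evolves at period granularity as

        m[t+1] = rho * m[t] + (1 - rho) * setpoint_i
                 + effect(regimen_t, covariates_i) + process noise,

    so the drug active during period t shifts the next period's mean SBP —
    the quantity the downstream models try to predict.  The truth table
    stores the noise-free transition target under every menu option.
    """
    rng = np.random.default_rng(config.seed)
    classes = list(config.drug_classes)
    frac = {**DEFAULT_RULE_TRIGGER_FRACTIONS, **config.rule_trigger_fractions}
    rho = config.ar_coefficient
    n_periods = config.horizon_days // config.visit_period
    period = config.visit_period

    meas_rows: list[tuple] = []
    anchor_rows: list[int] = []  # indices of timeline-origin SBP rows
    rx_rows: list[tuple] = []
    demo_rows: list[dict] = []
    truth_rows: list[tuple] = []
    latent_rows: list[dict] = []

    for pid in range(config.n_patients):
        age = float(np.clip(rng.normal(61.0, 12.0), 25.0, 95.0))
        sex = "F" if rng.random() < 0.52 else "M"
        race = rng.choice(["Black", "White", "Hispanic", "Other"], p=[0.50, 0.26, 0.09, 0.15])
        smoker = int(rng.random() < 0.28)
        diabetes = int(rng.random() < frac["diabetes"])
        systolic_hf = int(rng.random() < frac["systolic_hf"])
        athero_hd = int(rng.random() < 0.13)
        pvd = int(rng.random() < 0.07)
        htn_dx = int(rng.random() < 0.85)

        low_pulse = rng.random() < frac["low_pulse"]
        pulse_base = rng.normal(54.0, 2.5) if low_pulse else max(rng.normal(76.0, 8.0), 61.0)
        u = rng.random()
        if u < frac["k_gt_5"]:
            potassium_base = rng.uniform(5.1, 5.6)
        elif u < frac["k_gt_5"] + frac["k_gt_45"]:
            potassium_base = rng.uniform(4.55, 5.0)
        else:
            potassium_base = float(np.clip(rng.normal(4.1, 0.2), 3.3, 4.45))
        if rng.random() < frac["creat_ge_2"]:
            creatinine_base = rng.uniform(2.0, 3.2)
        else:
            creatinine_base = float(np.clip(rng.lognormal(-0.05, 0.2), 0.5, 1.9))
        spo2_base = float(np.clip(rng.normal(97.0, 1.3), 88.0, 100.0))

        trait_volume = rng.normal(0.0, 1.0)
        trait_ras = rng.normal(0.0, 1.0)
        setpoint = rng.normal(150.0, 12.0)
        covars = {
            "age_z": (age - 61.0) / 12.0,
            "diabetes": float(diabetes),
            "black": float(race == "Black"),
            "trait_volume": trait_volume,
            "trait_ras": trait_ras,
        }
        demo = {
            "patient_id": pid,
            "age": round(age, 1),
            "sex": sex,
            "race": race,
            "smoker": smoker,
            "diabetes": diabetes,
            "systolic_hf": systolic_hf,
            "athero_hd": athero_hd,
            "pvd": pvd,
            "htn_dx": htn_dx,
        }
        demo_rows.append(demo)
        latent_rows.append(
            {"patient_id": pid, "setpoint": setpoint, "trait_volume": trait_volume,
             "trait_ras": trait_ras, "pulse_base": pulse_base,
             "potassium_base": potassium_base, "creatinine_base": creatinine_base}
        )

        first_day = int(rng.integers(0, 30))
        scores = _behavior_scores(classes, demo, pulse_base)
        propensity = np.exp(scores - scores.max())
        propensity /= propensity.sum()

        def draw_regimen() -> tuple[str, ...]:
            if config.fixed_regimen is not None:
                return tuple(config.fixed_regimen)
            if rng.random() < config.combo_fraction:
                picks = rng.choice(len(classes), size=2, replace=False, p=propensity)
                return tuple(sorted(classes[j] for j in picks))
            return (classes[int(rng.choice(len(classes), p=propensity))],)

        m = setpoint + rng.normal(0.0, 1.0) * config.noise_sd
        if config.fixed_regimen is not None:
            regimen: tuple[str, ...] = tuple(config.fixed_regimen)
            treated = True
        else:
            treated = rng.random() < 1.0 / (1.0 + np.exp(-(m - 145.0) / 8.0))
            regimen = draw_regimen() if treated else ()

        for t in range(n_periods):
            p_start = first_day + period * t
            # prescription interval covering this period (inclusive days)
            for c in regimen:
                rx_rows.append((pid, p_start, p_start + period - 1, c))

            # measurements within the period; the very first SBP record sits
            # exactly at the patient's timeline origin so that downstream
            # period binning (anchored at the first observed SBP) coincides
            # with the generator's periods
            n_sbp = 1 + int(rng.poisson(1.0))
            offsets = np.sort(rng.choice(period, size=min(n_sbp, period), replace=False))
            if t == 0:
                offsets[0] = 0
            days = p_start + offsets
            for d in days:
                if t == 0 and d == p_start:
                    anchor_rows.append(len(meas_rows))
                sbp_val = m + rng.normal(0.0, 0.5) * config.noise_sd
                meas_rows.append((pid, int(d), "sbp", round(float(sbp_val), 2)))
                dbp_val = 0.55 * sbp_val + 8.0 + rng.normal(0.0, 0.5) * config.noise_sd
                meas_rows.append((pid, int(d), "dbp", round(float(dbp_val), 2)))
            lab_day = p_start + int(rng.integers(0, period))
            meas_rows.append((pid, lab_day, "pulse", round(float(pulse_base + rng.normal(0, 2.0)), 1)))
            meas_rows.append((pid, lab_day, "potassium", round(float(potassium_base + rng.normal(0, 0.05)), 2)))
            meas_rows.append((pid, lab_day, "creatinine", round(float(creatinine_base + rng.normal(0, 0.04)), 2)))
            meas_rows.append((pid, lab_day, "spo2", round(float(np.clip(spo2_base + rng.normal(0, 0.8), 85, 100)), 1)))

            # counterfactual truth for every menu option at this period
            if t < n_periods - 1:
                carry = rho * m + (1.0 - rho) * setpoint
                # quantized to 0.01 mmHg like the charted measurements
                for c in classes:
                    cf = carry + _regimen_effect((c,), config.effect_matrix, covars)
                    truth_rows.append((pid, t, c, round(float(cf), 2)))
                cf_cur = carry + _regimen_effect(regimen, config.effect_matrix, covars)
                truth_rows.append((pid, t, CURRENT_OPTION, round(float(cf_cur), 2)))

            # advance the trajectory under the logged (behavior) regimen
            m = (
                rho * m
                + (1.0 - rho) * setpoint
                + _regimen_effect(regimen, config.effect_matrix, covars)
                + rng.normal(0.0, 1.0) * config.noise_sd
            )

            # regimen dynamics for the next period
            if config.fixed_regimen is None:
                if not treated:
                    if rng.random() < 0.6 / (1.0 + np.exp(-(m - 145.0) / 8.0)):
                        treated = True
                        regimen = draw_regimen()
                elif rng.random() < 0.15:
                    regimen = draw_regimen()

    measurements = pd.DataFrame(meas_rows, columns=["patient_id", "day", "kind", "value"])
    if config.missing_fraction > 0 and len(measurements):
        keep = rng.random(len(measurements)) >= config.missing_fraction
        keep[np.asarray(anchor_rows, dtype=int)] = True  # anchors define the timeline
        measurements = measurements.loc[keep].reset_index(drop=True)
    measurements = measurements.sort_values(
        ["patient_id", "day", "kind"], kind="mergesort"
    ).reset_index(drop=True)

    prescriptions = pd.DataFrame(rx_rows, columns=["patient_id", "start_day", "end_day", "drug_class"])
    demographics = pd.DataFrame(demo_rows)
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "period_index", "option", "future_sbp"])

    cohort = SyntheticCohort(
        measurements=measurements,
        prescriptions=prescriptions,
        demographics=demographics,
        truth=truth,
        generative_params={
            "effect_matrix": {c: dict(v) for c, v in config.effect_matrix.items()},
            "latents": pd.DataFrame(latent_rows),
            "ar_coefficient": rho,
        },
        config=config,
    )
    if config.outlier_fraction > 0:
        cohort = contaminate_outcomes(
            cohort, config.outlier_fraction, config.outlier_magnitude, seed=config.seed + 1
        )
    return cohort


def contaminate_outcomes(
    cohort: SyntheticCohort, fraction: float, magnitude: float, seed: int
) -> SyntheticCohort:
    """Corrupt a fixed fraction of SBP measurements by +/- magnitude mmHg.

    Emulates entry errors: exactly ``round(fraction * n_sbp)`` measurement
    rows are shifted; the counterfactual truth table is left untouched
    (errors live in the observations, not in the underlying physiology).
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"contamination fraction must be in [0, 1), got {fraction}")
    out = cohort.copy()
    if fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)
    sbp_idx = out.measurements.index[out.measurements["kind"] == "sbp"].to_numpy()
    n_corrupt = int(round(fraction * len(sbp_idx)))
    if n_corrupt == 0:
        return out
    chosen = rng.choice(sbp_idx, size=n_corrupt, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_corrupt)
    out.measurements.loc[chosen, "value"] = (
        out.measurements.loc[chosen, "value"].to_numpy() + signs * magnitude
    )
    return out
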