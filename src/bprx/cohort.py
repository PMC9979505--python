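"""Visit-level analysis table construction from raw EHR event streams.

Patients are screened by hypertension criteria, their timelines cut into
90-day review periods anchored at the first SBP record, time-varying
measurements averaged within each period, the active drug-class regimen
attached, and the outcome — the average SBP over a window one period ahead
— joined on.  The result is the modeling table every downstream stage
consumes.

Conventions
-----------
* Period bins are half-open ``[start, start + period)``; a measurement
  exactly at ``start + period`` belongs to the next period.
* The outcome for the visit starting at ``s`` is the mean SBP over
  ``[s + offset, s + offset + period)`` with ``offset`` defaulting to one
  period (i.e. the next visit); visits with no SBP measurement in that
  window have a missing outcome and are dropped from modeling.
* Regimens are stored as ``"+"``-joined sorted class strings
  (``"ACEi+Thiazide"``; the empty string means untreated).
* Feature standardization (and median imputation of residual gaps) is fit
  on training data only and then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import DRUG_CLASSES, NO_REGIMEN, SyntheticCohort

#: metadata columns of a visit table (everything else is a feature column)
META_COLUMNS = (
    "visit_id",
    "patient_id",
    "period_index",
    "period_start",
    "regimen",
    "future_sbp",
    "prior_exposure",
)

# vitals/labs averaged per period and carried forward when a period lacks them
_TIME_VARYING_KINDS = ("sbp", "dbp", "pulse", "potassium", "creatinine", "spo2")


def regimen_string(classes) -> str:
    return "+".join(sorted(classes))


def regimen_set(regimen: str) -> frozenset[str]:
    return frozenset(regimen.split("+")) if regimen else frozenset()


@dataclass
class VisitRecord:
    """One 90-day review period of one patient."""

    visit_id: int
    patient_id: int
    period_index: int
    period_start: int
    features: np.ndarray
    regimen: frozenset[str]
    current_sbp: float
    future_sbp: float  # NaN when the outcome window is empty


@dataclass
class FeatureSchema:
    """Ordered feature set with train-frozen standardization statistics."""

    names: list[str]
    kinds: dict[str, str]  # name -> "numeric" | "binary"
    means: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)
    medians: dict[str, float] = field(default_factory=dict)
    fitted: bool = False

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        unknown = [n for n in self.names if self.kinds.get(n) not in ("numeric", "binary")]
        if unknown:
            raise ValueError(f"features without a valid kind: {unknown}")

    @property
    def p(self) -> int:
        return len(self.names)

    def fit(self, train_visits: pd.DataFrame) -> "FeatureSchema":
        """Learn imputation medians and z-score statistics from training visits."""
        for name in self.names:
            col = pd.to_numeric(train_visits[name], errors="coerce")
            med = float(col.median()) if col.notna().any() else 0.0
            self.medians[name] = med
            if self.kinds[name] == "numeric":
                filled = col.fillna(med)
                self.means[name] = float(filled.mean())
                sd = float(filled.std(ddof=0))
                self.scales[name] = sd if sd > 0 else 1.0
            else:
                self.means[name] = 0.0
                self.scales[name] = 1.0
        self.fitted = True
        return self

    def transform(self, visits: pd.DataFrame) -> np.ndarray:
        """Impute residual gaps with train medians and z-score numeric features."""
        if not self.fitted:
            raise RuntimeError("FeatureSchema must be fitted on training data first")
        out = np.empty((len(visits), self.p), dtype=float)
        for j, name in enumerate(self.names):
            col = pd.to_numeric(visits[name], errors="coerce").fillna(self.medians[name])
            out[:, j] = (col.to_numpy(dtype=float) - self.means[name]) / self.scales[name]
        return out


def default_schema() -> FeatureSchema:
    """Feature set covering the named EHR categories: BP history, vitals,
    labs, demographics, comorbidities, smoking and medication history."""
    numeric = [
        "current_sbp", "current_dbp", "sbp_lag1", "sbp_lag2",
        "pulse", "potassium", "creatinine", "spo2", "age",
        "n_active_classes", "n_prior_classes",
    ]
    binary = [
        "female", "race_black", "race_white", "race_hispanic",
        "smoker", "diabetes", "systolic_hf", "athero_hd", "pvd",
    ]
    kinds = {n: "numeric" for n in numeric} | {n: "binary" for n in binary}
    return FeatureSchema(names=numeric + binary, kinds=kinds)


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing columns {missing}")


def load_event_tables(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read measurements/prescriptions/demographics CSVs from a directory."""
    in_dir = Path(in_dir)
    measurements = pd.read_csv(in_dir / "measurements.csv")
    prescriptions = pd.read_csv(in_dir / "prescriptions.csv")
    demographics = pd.read_csv(in_dir / "demographics.csv")
    return measurements, prescriptions, demographics


def select_cohort(
    measurements: pd.DataFrame,
    prescriptions: pd.DataFrame,
    demographics: pd.DataFrame,
    drug_classes=DRUG_CLASSES,
    window_days: int = 180,
) -> set[int]:
    """Apply the inclusion criteria and return qualifying patient ids.

    A patient qualifies when (hypertension diagnosis OR problem-list flag
    OR any SBP > 130 OR any DBP > 90) AND at least two SBP measurements
    within some ``window_days`` span AND at least one prescription among
    the recognised antihypertensive classes.
    """
    _require_columns(measurements, ["patient_id", "day", "kind", "value"], "measurements")
    _require_columns(prescriptions, ["patient_id", "drug_class"], "prescriptions")
    _require_columns(demographics, ["patient_id"], "demographics")
    if (measurements["day"] < 0).any():
        bad = int(measurements.index[measurements["day"] < 0][0])
        raise ValueError(f"measurements row {bad}: negative day stamp")

    dx_cols = [c for c in ("htn_dx", "htn_problem_list") if c in demographics.columns]
    dx_flag = demographics[dx_cols].any(axis=1) if dx_cols else pd.Series(False, index=demographics.index)
    dx_patients = set(demographics.loc[dx_flag.astype(bool), "patient_id"])

    sbp = measurements[measurements["kind"] == "sbp"]
    dbp = measurements[measurements["kind"] == "dbp"]
    high_bp = set(sbp.loc[sbp["value"] > 130, "patient_id"]) | set(
        dbp.loc[dbp["value"] > 90, "patient_id"]
    )

    def has_pair_within(days: pd.Series) -> bool:
        d = np.sort(days.to_numpy())
        return len(d) >= 2 and bool((np.diff(d) <= window_days).any())

    paired = {pid for pid, grp in sbp.groupby("patient_id")["day"] if has_pair_within(grp)}

    treated = set(
        prescriptions.loc[prescriptions["drug_class"].isin(drug_classes), "patient_id"]
    )
    return (dx_patients | high_bp) & paired & treated


def build_visits(
    measurements: pd.DataFrame,
    prescriptions: pd.DataFrame,
    demographics: pd.DataFrame,
    patient_ids=None,
    period: int = 90,
) -> pd.DataFrame:
    """Bin each patient's timeline into visits and assemble raw features.

    Returns a visit table with one row per (patient, period) from the first
    SBP record to the last, metadata columns (``META_COLUMNS``) plus raw
    feature columns.  Periods lacking a vital/lab carry the last observed
    value forward within the patient; anything still missing is left NaN for
    the schema's train-median imputation.
    """
    demo = demographics.set_index("patient_id")
    if patient_ids is None:
        patient_ids = sorted(set(measurements.loc[measurements["kind"] == "sbp", "patient_id"]))

    rx = prescriptions.sort_values(["patient_id", "start_day"])
    rx_by_patient = {pid: grp for pid, grp in rx.groupby("patient_id")}
    meas_by_patient = {pid: grp for pid, grp in measurements.groupby("patient_id")}

    rows = []
    for pid in patient_ids:
        grp = meas_by_patient.get(pid)
        if grp is None:
            continue
        sbp_days = grp.loc[grp["kind"] == "sbp", "day"]
        if sbp_days.empty:
            continue
        anchor = int(sbp_days.min())
        last = int(sbp_days.max())
        n_periods = (last - anchor) // period + 1

        prx = rx_by_patient.get(pid)
        d = demo.loc[pid]
        period_means: dict[str, list[float]] = {k: [] for k in _TIME_VARYING_KINDS}
        for t in range(n_periods):
            p_start = anchor + period * t
            p_end = p_start + period
            in_bin = grp[(grp["day"] >= p_start) & (grp["day"] < p_end)]
            for kind in _TIME_VARYING_KINDS:
                vals = in_bin.loc[in_bin["kind"] == kind, "value"]
                period_means[kind].append(float(vals.mean()) if len(vals) else np.nan)

            if prx is not None:
                active = prx[(prx["start_day"] < p_end) & (prx["end_day"] >= p_start)]
                regimen = regimen_string(set(active["drug_class"]))
                prior = prx[prx["start_day"] < p_start]
                n_prior = prior["drug_class"].nunique()
            else:
                regimen, n_prior = NO_REGIMEN, 0

            rows.append(
                {
                    "patient_id": pid,
                    "period_index": t,
                    "period_start": p_start,
                    "regimen": regimen,
                    "prior_exposure": n_prior > 0,
                    "current_sbp": period_means["sbp"][t],
                    "current_dbp": period_means["dbp"][t],
                    "pulse": period_means["pulse"][t],
                    "potassium": period_means["potassium"][t],
                    "creatinine": period_means["creatinine"][t],
                    "spo2": period_means["spo2"][t],
                    "sbp_lag1": period_means["sbp"][t - 1] if t >= 1 else np.nan,
                    "sbp_lag2": period_means["sbp"][t - 2] if t >= 2 else np.nan,
                    "n_active_classes": len(regimen_set(regimen)),
                    "n_prior_classes": n_prior,
                    "age": float(d["age"]),
                    "female": int(d["sex"] == "F"),
                    "race_black": int(d["race"] == "Black"),
                    "race_white": int(d["race"] == "White"),
                    "race_hispanic": int(d["race"] == "Hispanic"),
                    "smoker": int(d["smoker"]),
                    "diabetes": int(d["diabetes"]),
                    "systolic_hf": int(d["systolic_hf"]),
                    "athero_hd": int(d["athero_hd"]),
                    "pvd": int(d["pvd"]),
                }
            )

    visits = pd.DataFrame(rows)
    if visits.empty:
        return visits
    # last-observation-carried-forward for vitals/labs within patient
    locf_cols = ["current_dbp", "pulse", "potassium", "creatinine", "spo2", "sbp_lag1", "sbp_lag2"]
    visits[locf_cols] = visits.groupby("patient_id")[locf_cols].ffill()
    visits.insert(0, "visit_id", np.arange(len(visits)))
    visits["future_sbp"] = np.nan
    return visits


def attach_outcomes(
    visits: pd.DataFrame,
    measurements: pd.DataFrame,
    offset: int = 90,
    window: int = 90,
) -> pd.DataFrame:
    """Attach the future-SBP outcome: mean SBP over [start+offset, start+offset+window)."""
    out = visits.copy()
    sbp = measurements[measurements["kind"] == "sbp"]
    sbp_by_patient = {pid: grp for pid, grp in sbp.groupby("patient_id")}
    y = np.full(len(out), np.nan)
    for i, (pid, p_start) in enumerate(zip(out["patient_id"], out["period_start"])):
        grp = sbp_by_patient.get(pid)
        if grp is None:
            continue
        lo, hi = p_start + offset, p_start + offset + window
        vals = grp.loc[(grp["day"] >= lo) & (grp["day"] < hi), "value"]
        if len(vals):
            y[i] = float(vals.mean())
    out["future_sbp"] = y
    return out


def modeling_table(visits: pd.DataFrame) -> pd.DataFrame:
    """Visits with a valid future outcome (the rest are dropped from modeling)."""
    return visits[visits["future_sbp"].notna()].reset_index(drop=True)


def split_by_patient(
    visits: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Patient-disjoint train/validation/test split at the given proportions.

    Patients — not visits — are partitioned, so no individual contributes
    rows to more than one set.  Counts use largest-remainder allocation so
    e.g. 10 patients at (0.8, 0.1, 0.1) split exactly 8/1/1.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    patients = np.array(sorted(visits["patient_id"].unique()))
    if len(patients) < 3:
        raise ValueError(f"need at least 3 patients to split, got {len(patients)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)

    n = len(patients)
    raw = np.array(fractions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    for j in np.argsort(-(raw - counts))[:remainder]:
        counts[j] += 1

    bounds = np.cumsum(counts)
    groups = np.split(patients, bounds[:-1])
    return tuple(
        visits[visits["patient_id"].isin(set(g))].reset_index(drop=True) for g in groups
    )


def visit_records(visits: pd.DataFrame, schema: FeatureSchema) -> list[VisitRecord]:
    """Materialize dataclass views of a visit table under a fitted schema."""
    X = schema.transform(visits)
    return [
        VisitRecord(
            visit_id=int(r.visit_id),
            patient_id=int(r.patient_id),
            period_index=int(r.period_index),
            period_start=int(r.period_start),
            features=X[i],
            regimen=regimen_set(r.regimen),
            current_sbp=float(r.current_sbp),
            future_sbp=float(r.future_sbp) if pd.notna(r.future_sbp) else float("nan"),
        )
        for i, r in enumerate(visits.itertuples())
    ]


def build_visit_table(
    cohort_or_dir,
    period: int = 90,
    outcome_offset: int = 90,
    apply_inclusion: bool = True,
) -> pd.DataFrame:
    """End-to-end convenience: events -> inclusion -> visits -> outcomes."""
    if isinstance(cohort_or_dir, SyntheticCohort):
        measurements = cohort_or_dir.measurements
        prescriptions = cohort_or_dir.prescriptions
        demographics = cohort_or_dir.demographics
    else:
        measurements, prescriptions, demographics = load_event_tables(cohort_or_dir)
    ids = None
    if apply_inclusion:
        ids = sorted(select_cohort(measurements, prescriptions, demographics))
    visits = build_visits(measurements, prescriptions, demographics, patient_ids=ids, period=period)
    if visits.empty:
        return visits
    return attach_outcomes(visits, measurements, offset=outcome_offset, window=period)
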