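"""Evaluation protocol: algorithm comparison, subgroup and profile analyses.

Reproduces the study-style comparison layout on any cohort: per-algorithm
mean next-period SBP reduction across repeated patient-disjoint splits,
against two references — *standard of care* (the observed outcome under
the prescription actually given) and *current regimen* (the counterfactual
of continuing the active prescription unchanged).  On synthetic cohorts the
generator's counterfactual truth table supplies an additional, estimation-
free reduction for any policy, which is what the end-to-end value checks
use.

Reductions follow the negative-sign convention: a visit whose current SBP
is 150 and whose (predicted or observed) next-period SBP is 136 scores a
reduction of -14 mmHg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import FeatureSchema, default_schema, modeling_table, regimen_set, split_by_patient
from .neighbors import (
    UNTREATED,
    CounterfactualPanel,
    build_panels,
    build_pools,
)
from .policy import PolicyConfig, Recommendation, apply_rules, recommend_all
from .regression import FittedRegressor, fit_algorithm
from .synthetic import CURRENT_OPTION, DRUG_CLASSES, NO_REGIMEN

KNN_ALGORITHMS = ("DRLR", "OLS")  # coefficient-weighted KNN predictors
DIRECT_ALGORITHMS = ("LASSO", "CART")  # predict straight from the regression


def percent_improvement(a: float, b: float) -> float:
    """How much larger reduction ``a`` is than reference reduction ``b``, in %.

    Both arguments are signed mmHg reductions; the comparison is on
    magnitudes: ``(|a| - |b|) / |b| * 100``.
    """
    if b == 0:
        raise ValueError("reference reduction must be nonzero")
    return (abs(a) - abs(b)) / abs(b) * 100.0


# ---------------------------------------------------------------------------
# model fitting and panel construction


def fit_submodels(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    schema: FeatureSchema,
    algorithm: str,
    drug_classes=DRUG_CLASSES,
    tune: bool = False,
    min_rows: int = 30,
    **fit_kwargs,
) -> dict[str, FittedRegressor]:
    """One outcome regression per drug class (plus the untreated pool).

    A class's training rows are the modeling visits whose regimen includes
    that class (combination regimens contribute to each constituent).
    Classes with fewer than ``min_rows`` usable rows are skipped, which
    downstream surfaces as an omitted menu option.
    """
    train_m = modeling_table(train)
    val_m = modeling_table(validation) if validation is not None else None
    Xtr = schema.transform(train_m)
    ytr = train_m["future_sbp"].to_numpy(dtype=float)
    regimens = train_m["regimen"].fillna(NO_REGIMEN).to_numpy()
    if val_m is not None and len(val_m):
        Xv = schema.transform(val_m)
        yv = val_m["future_sbp"].to_numpy(dtype=float)
        val_regimens = val_m["regimen"].fillna(NO_REGIMEN).to_numpy()
    else:
        Xv = yv = val_regimens = None

    models: dict[str, FittedRegressor] = {}
    keys = list(drug_classes) + [UNTREATED]
    for key in keys:
        if key == UNTREATED:
            mask = regimens == NO_REGIMEN
        else:
            mask = np.array([key in regimen_set(r) for r in regimens])
        if mask.sum() < min_rows:
            continue
        val_pair = None
        if tune and Xv is not None:
            if key == UNTREATED:
                vmask = val_regimens == NO_REGIMEN
            else:
                vmask = np.array([key in regimen_set(r) for r in val_regimens])
            if vmask.sum() >= 5:
                val_pair = (Xv[vmask], yv[vmask])
        models[key] = fit_algorithm(
            algorithm, Xtr[mask], ytr[mask],
            validation=val_pair, drug_class=key,
            feature_names=schema.names, **fit_kwargs,
        )
    return models


def build_direct_panels(
    visits: pd.DataFrame,
    schema: FeatureSchema,
    models: dict[str, FittedRegressor],
    drug_classes=DRUG_CLASSES,
) -> list[CounterfactualPanel]:
    """Panels where each option's prediction comes straight from its
    regression (LASSO/CART mode — no neighbor search).

    The current-regimen option for a combination is the mean of the
    constituent class predictions; for an untreated visit it comes from
    the untreated-pool model.
    """
    X = schema.transform(visits)
    panels = []
    preds = {c: models[c].predict(X) for c in drug_classes if c in models}
    untreated_pred = models[UNTREATED].predict(X) if UNTREATED in models else None
    for i, row in enumerate(visits.itertuples()):
        reg = row.regimen if isinstance(row.regimen, str) else NO_REGIMEN
        panel = CounterfactualPanel(visit_id=int(row.visit_id), regimen=reg)
        for c in drug_classes:
            if c in preds:
                panel.predictions[c] = float(preds[c][i])
            else:
                panel.flags[c] = "no_model"
        classes = sorted(regimen_set(reg))
        if len(classes) == 1 and classes[0] in panel.predictions:
            panel.current_alias = classes[0]
            panel.predictions[CURRENT_OPTION] = panel.predictions[classes[0]]
        elif classes:
            parts = [panel.predictions[c] for c in classes if c in panel.predictions]
            if parts:
                panel.predictions[CURRENT_OPTION] = float(np.mean(parts))
        elif untreated_pred is not None:
            panel.predictions[CURRENT_OPTION] = float(untreated_pred[i])
        panels.append(panel)
    return panels


def run_split(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    test: pd.DataFrame,
    algorithm: str = "DRLR",
    schema: Optional[FeatureSchema] = None,
    k: int = 50,
    policy: Optional[PolicyConfig] = None,
    truth: Optional[pd.DataFrame] = None,
    drug_classes=DRUG_CLASSES,
    tune: bool = False,
    **fit_kwargs,
) -> dict:
    """Fit -> panels -> recommend -> evaluate for one split and algorithm."""
    if schema is None:
        schema = default_schema()
    if not schema.fitted:
        schema.fit(modeling_table(train))
    policy = policy or PolicyConfig()
    models = fit_submodels(
        train, validation, schema, algorithm, drug_classes, tune=tune, **fit_kwargs
    )
    test_m = modeling_table(test)
    if algorithm.upper() in DIRECT_ALGORITHMS:
        panels = build_direct_panels(test_m, schema, models, drug_classes)
    else:
        pools = build_pools(train, schema, drug_classes)
        panels = build_panels(test_m, schema, models, pools, k, drug_classes)
    recs = recommend_all(panels, test_m, policy)
    reductions = evaluate_split(test_m, panels, recs, truth=truth)
    return {
        "schema": schema, "models": models, "panels": panels,
        "recs": recs, "reductions": reductions,
    }


# ---------------------------------------------------------------------------
# per-visit reductions


def evaluate_split(
    test_visits: pd.DataFrame,
    panels: list[CounterfactualPanel],
    recommendations: list[Recommendation],
    truth: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-visit signed SBP reductions for one evaluated split.

    Columns: ``model_reduction`` (predicted outcome under the chosen option
    minus current SBP), ``soc_reduction`` (observed outcome minus current
    SBP — standard of care), ``current_reduction`` (predicted outcome under
    the unchanged regimen minus current SBP), and, when a counterfactual
    truth table is supplied, ``truth_model_reduction`` /
    ``truth_current_reduction`` computed from it.
    """
    by_panel = {p.visit_id: p for p in panels}
    by_rec = {r.visit_id: r for r in recommendations}
    truth_map = None
    if truth is not None:
        truth_map = {
            (int(r.patient_id), int(r.period_index), r.option): float(r.future_sbp)
            for r in truth.itertuples()
        }

    rows = []
    for v in modeling_table(test_visits).itertuples():
        vid = int(v.visit_id)
        panel = by_panel.get(vid)
        if panel is None:
            raise KeyError(f"no counterfactual panel for visit {vid}")
        rec = by_rec.get(vid)
        if rec is None or not panel.predictions:
            continue
        cur_sbp = float(v.current_sbp)
        chosen = rec.chosen
        chosen_key = chosen if chosen in panel.predictions else CURRENT_OPTION
        row = {
            "visit_id": vid,
            "patient_id": int(v.patient_id),
            "period_index": int(v.period_index),
            "chosen": chosen,
            "kept_current": rec.kept_current,
            "model_reduction": panel.predictions[chosen_key] - cur_sbp,
            "soc_reduction": float(v.future_sbp) - cur_sbp,
            "current_reduction": (
                panel.predictions[CURRENT_OPTION] - cur_sbp
                if CURRENT_OPTION in panel.predictions else np.nan
            ),
        }
        if truth_map is not None:
            t_opt = CURRENT_OPTION if chosen_key == CURRENT_OPTION else chosen_key
            key = (int(v.patient_id), int(v.period_index), t_opt)
            key_cur = (int(v.patient_id), int(v.period_index), CURRENT_OPTION)
            row["truth_model_reduction"] = (
                truth_map[key] - cur_sbp if key in truth_map else np.nan
            )
            row["truth_current_reduction"] = (
                truth_map[key_cur] - cur_sbp if key_cur in truth_map else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def random_policy_truth_reduction(
    test_visits: pd.DataFrame,
    panels: list[CounterfactualPanel],
    truth: pd.DataFrame,
    seed: int = 0,
) -> float:
    """Mean truth-based reduction of a uniform-over-allowed-options policy.

    The reference policy for end-to-end value checks: it obeys the same
    hard clinical rules but ignores the counterfactual predictions.
    """
    rng = np.random.default_rng(seed)
    byid = test_visits.set_index("visit_id")
    cols = ["pulse", "potassium", "creatinine", "diabetes", "systolic_hf"]
    truth_map = {
        (int(r.patient_id), int(r.period_index), r.option): float(r.future_sbp)
        for r in truth.itertuples()
    }
    reds = []
    for p in panels:
        if not p.predictions:
            continue
        row = byid.loc[p.visit_id]
        if pd.isna(row["future_sbp"]) or pd.isna(row["current_sbp"]):
            continue
        visit = {c: (float(row[c]) if pd.notna(row[c]) else float("nan")) for c in cols}
        allowed, _, _, _ = apply_rules(visit, p.options(), p.regimen)
        if not allowed:
            allowed = [p.current_alias or CURRENT_OPTION]
        pick = allowed[int(rng.integers(len(allowed)))]
        t_opt = CURRENT_OPTION if pick == CURRENT_OPTION else pick
        key = (int(row["patient_id"]), int(row["period_index"]), t_opt)
        if key in truth_map:
            reds.append(truth_map[key] - float(row["current_sbp"]))
    return float(np.mean(reds)) if reds else float("nan")


# ---------------------------------------------------------------------------
# repeated-split comparison report


@dataclass
class EvaluationReport:
    """Algorithm-comparison table plus the per-split raw means behind it."""

    table: pd.DataFrame  # rows: (algorithm, mode) and the two references
    per_split: dict = field(default_factory=dict)
    n_splits: int = 0
    truth_table: Optional[pd.DataFrame] = None


def repeated_splits(
    visits: pd.DataFrame,
    algorithms: Sequence[str] = ("LASSO", "CART", "OLS", "DRLR"),
    modes: Sequence[str] = ("deterministic", "randomized"),
    n_splits: int = 5,
    seed: int = 0,
    k: int = 50,
    policy: Optional[PolicyConfig] = None,
    truth: Optional[pd.DataFrame] = None,
    fractions=(0.8, 0.1, 0.1),
    algo_params: Optional[dict[str, dict]] = None,
) -> EvaluationReport:
    """Full pipeline over repeated patient-disjoint splits.

    For each split and algorithm the sub-models are refitted from scratch,
    panels and recommendations rebuilt, and the mean per-visit reduction
    recorded; the report table gives mean and SD across splits for every
    (algorithm, mode) pair plus the current-regimen and standard-of-care
    references.
    """
    if n_splits < 2:
        raise ValueError(f"need at least 2 splits, got {n_splits}")
    policy = policy or PolicyConfig()
    cells: dict[tuple[str, str], list[float]] = {}
    counts: dict[tuple[str, str], int] = {}
    per_split: dict[int, dict] = {}
    truth_cells: dict[tuple[str, str], list[float]] = {}

    for s in range(n_splits):
        split_seed = seed + s
        train, val, test = split_by_patient(visits, fractions, seed=split_seed)
        schema = default_schema().fit(modeling_table(train))
        split_record: dict[str, float] = {}
        for algo in algorithms:
            for mode in modes:
                cfg = policy.model_copy(update={"mode": mode, "seed": split_seed})
                res = run_split(
                    train, val, test, algorithm=algo, schema=schema, k=k,
                    policy=cfg, truth=truth, **(algo_params or {}).get(algo, {}),
                )
                red = res["reductions"]
                key = (algo if algo in DIRECT_ALGORITHMS else f"{algo}+KNN", mode)
                cells.setdefault(key, []).append(float(red["model_reduction"].mean()))
                counts[key] = counts.get(key, 0) + len(red)
                split_record[f"{key[0]}/{mode}"] = cells[key][-1]
                if truth is not None and "truth_model_reduction" in red:
                    truth_cells.setdefault(key, []).append(
                        float(red["truth_model_reduction"].mean())
                    )
                if algo == algorithms[-1] and mode == modes[-1]:
                    for ref, col in (
                        ("Current regimen", "current_reduction"),
                        ("Standard of care", "soc_reduction"),
                    ):
                        cells.setdefault((ref, "-"), []).append(float(red[col].mean()))
                        counts[(ref, "-")] = counts.get((ref, "-"), 0) + len(red)
        per_split[split_seed] = split_record

    rows = [
        {
            "algorithm": alg, "mode": mode,
            "mean_reduction": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "n_visits": counts[(alg, mode)],
        }
        for (alg, mode), v in cells.items()
    ]
    table = pd.DataFrame(rows)
    truth_df = None
    if truth_cells:
        truth_df = pd.DataFrame(
            [
                {"algorithm": alg, "mode": mode,
                 "mean_truth_reduction": float(np.mean(v)),
                 "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
                for (alg, mode), v in truth_cells.items()
            ]
        )
    return EvaluationReport(
        table=table, per_split=per_split, n_splits=n_splits, truth_table=truth_df
    )


# ---------------------------------------------------------------------------
# subgroup and interpretation analyses


_PROFILE_BINARY = ("diabetes", "systolic_hf", "athero_hd", "pvd")


def deprescribing_analysis(
    test_visits: pd.DataFrame,
    reductions: pd.DataFrame,
) -> dict:
    """Monotherapy-for-polytherapy subgroup: visits on >= 2 drug classes.

    Compares the model's (monotherapy) reduction against standard of care
    per visit, counts the visits where the model does better, and summarizes
    the covariates of that beneficiary subgroup against the whole test set.
    """
    visits = test_visits.set_index("visit_id")
    merged = reductions.join(
        visits[["regimen", "age", *_PROFILE_BINARY]], on="visit_id"
    )
    n_classes = merged["regimen"].fillna(NO_REGIMEN).map(lambda r: len(regimen_set(r)))
    combo = merged[n_classes >= 2]
    out = {
        "n_combo_visits": int(len(combo)),
        "mean_model_reduction": float(combo["model_reduction"].mean()) if len(combo) else np.nan,
        "mean_soc_reduction": float(combo["soc_reduction"].mean()) if len(combo) else np.nan,
    }
    if not len(combo):
        out.update({"n_better": 0, "fraction_better_pct": np.nan, "profile": pd.DataFrame()})
        return out
    better = combo[combo["model_reduction"] < combo["soc_reduction"]]
    out["n_better"] = int(len(better))
    out["fraction_better_pct"] = 100.0 * len(better) / len(combo)

    def summarize(df, label):
        row = {"group": label, "n": int(len(df)), "mean_age": float(df["age"].mean())}
        for c in _PROFILE_BINARY:
            row[f"{c}_pct"] = 100.0 * float(df[c].mean())
        return row

    test_m = modeling_table(test_visits)
    out["profile"] = pd.DataFrame(
        [summarize(test_m, "all_test_visits"), summarize(better, "effective_deprescribing")]
    )
    return out


def neighborhood_profiles(
    recommendations: list[Recommendation],
    panels: list[CounterfactualPanel],
    train_visits: pd.DataFrame,
    baseline_visits: pd.DataFrame,
    numeric_features: Sequence[str] = ("age", "current_sbp"),
    binary_features: Sequence[str] = ("female", "race_black", "race_white", "diabetes"),
) -> pd.DataFrame:
    """Per-class affinity profiles: pooled neighbor sets behind each class.

    For every recommendation of class c, the K neighbors behind the winning
    option are pooled (across all such recommendations); the profile reports
    per-feature means and subgroup percentages over that pool, next to the
    test-set baseline row.
    """
    by_panel = {p.visit_id: p for p in panels}
    train = train_visits.set_index("visit_id")
    pooled: dict[str, list[np.ndarray]] = {}
    for rec in recommendations:
        panel = by_panel.get(rec.visit_id)
        if panel is None:
            continue
        chosen = rec.chosen
        key = chosen if chosen in panel.neighbor_ids else CURRENT_OPTION
        ids = panel.neighbor_ids.get(key)
        if ids is None or (chosen == CURRENT_OPTION and panel.current_alias is None):
            # profiles are per drug class; an unaliased "current" has no class
            if chosen == CURRENT_OPTION:
                continue
        label = panel.current_alias if chosen == CURRENT_OPTION else chosen
        if ids is not None and label is not None:
            pooled.setdefault(label, []).append(ids)

    rows = []

    def profile_row(df, label, n):
        row = {"class": label, "n_pooled": n}
        for f in numeric_features:
            row[f"mean_{f}"] = float(df[f].mean()) if len(df) else np.nan
        for f in binary_features:
            row[f"{f}_pct"] = 100.0 * float(df[f].mean()) if len(df) else np.nan
        return row

    for label, id_lists in sorted(pooled.items()):
        ids = np.concatenate(id_lists)
        sub = train.loc[[i for i in ids if i in train.index]]
        rows.append(profile_row(sub, label, len(ids)))
    rows.append(profile_row(modeling_table(baseline_visits), "test_set_baseline",
                            len(modeling_table(baseline_visits))))
    return pd.DataFrame(rows)


def aggregate_importance(models: Sequence[FittedRegressor]) -> pd.DataFrame:
    """Cross-class feature importances: mean of per-model unit-sum |beta|.

    Every sub-model's |coefficients| are normalized to sum one before
    averaging, so no single class dominates; the resulting scores again sum
    to one and rank features exactly as a grouped importance chart would.
    """
    models = list(models)
    names = models[0].feature_names
    for m in models[1:]:
        if m.feature_names != names:
            raise ValueError("sub-models disagree on the feature schema")
    mat = []
    for m in models:
        w = np.abs(m.coef_).astype(float)
        total = w.sum()
        mat.append(w / total if total > 0 else w)
    scores = np.mean(mat, axis=0)
    if names is None:
        names = [f"x{i}" for i in range(len(scores))]
    return (
        pd.DataFrame({"feature": names, "score": scores})
        .sort_values("score", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def naive_initiation_analysis(
    test_visits: pd.DataFrame,
    recommendations: list[Recommendation],
    reductions: Optional[pd.DataFrame] = None,
) -> dict:
    """Treatment initiation in the clinical-equipoise subgroup.

    Restricts to non-diabetic visits with no antihypertensive exposure in
    any prior period and none active, and reports the share of each
    recommended class plus the subgroup's mean (predicted) reduction.
    """
    visits = modeling_table(test_visits)
    naive = visits[
        (visits["diabetes"] == 0)
        & (~visits["prior_exposure"].astype(bool))
        & (visits["regimen"].fillna(NO_REGIMEN) == NO_REGIMEN)
    ]
    naive_ids = set(naive["visit_id"])
    by_rec = {r.visit_id: r for r in recommendations}
    chosen = [
        by_rec[v].chosen if by_rec[v].chosen != CURRENT_OPTION else "none"
        for v in naive_ids if v in by_rec
    ]
    out = {"n_naive_visits": len(chosen)}
    if chosen:
        shares = pd.Series(chosen).value_counts(normalize=True) * 100.0
        out["class_shares_pct"] = shares.to_dict()
    else:
        out["class_shares_pct"] = {}
    if reductions is not None and len(chosen):
        sub = reductions[reductions["visit_id"].isin(naive_ids)]
        out["mean_model_reduction"] = float(sub["model_reduction"].mean())
    return out


def export_dossiers(
    recommendations: list[Recommendation],
    panels: list[CounterfactualPanel],
    visits: pd.DataFrame,
    profiles: Optional[pd.DataFrame],
    n: int,
    seed: int = 0,
    path: Optional[str | Path] = None,
) -> list[dict]:
    """Seeded sample of n recommendation dossiers for clinician review.

    Each dossier packages the visit's features, the full counterfactual
    panel, the policy probabilities and exclusions, the chosen option, and
    the recommended class's neighborhood profile — a machine-readable
    review packet.
    """
    if n > len(recommendations):
        raise ValueError(
            f"requested {n} dossiers but only {len(recommendations)} recommendations exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(recommendations), size=n, replace=False)
    by_panel = {p.visit_id: p for p in panels}
    byid = visits.set_index("visit_id")
    profile_by_class = {}
    if profiles is not None and len(profiles):
        profile_by_class = {
            r["class"]: {k: v for k, v in r.items() if k != "class"}
            for r in profiles.to_dict("records")
        }
    dossiers = []
    for i in sorted(int(j) for j in idx):
        rec = recommendations[i]
        panel = by_panel[rec.visit_id]
        row = byid.loc[rec.visit_id]
        label = panel.current_alias if rec.chosen == CURRENT_OPTION else rec.chosen
        dossiers.append(
            {
                "visit_id": int(rec.visit_id),
                "patient_id": int(row["patient_id"]),
                "regimen": panel.regimen,
                "features": {
                    c: (None if pd.isna(row[c]) else float(row[c]))
                    for c in ("age", "current_sbp", "pulse", "potassium",
                              "creatinine", "diabetes", "systolic_hf")
                    if c in row.index
                },
                "panel": {k: float(v) for k, v in panel.predictions.items()},
                "probabilities": {k: float(v) for k, v in rec.probabilities.items()},
                "exclusions": rec.excluded,
                "chosen": rec.chosen,
                "kept_current": rec.kept_current,
                "neighborhood_profile": profile_by_class.get(label),
            }
        )
    if path is not None:
        Path(path).write_text(json.dumps(dossiers, indent=2))
    return dossiers
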