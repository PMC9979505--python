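"""Coefficient-weighted K-nearest-neighbor counterfactual prediction.

The core estimator of the pipeline: to predict a visit's next-period SBP
under drug class m, the per-class regression coefficients beta_m weight a
distance between standardized feature vectors,

    d(x, z) = sqrt( sum_i (x_i - z_i)^2 * beta_i^2 ),

the K closest training visits that were actually on m are found under that
metric, and the unweighted average of their observed future SBP values is
the counterfactual prediction y_hat_m.  Repeating over the whole menu of
options (7 monotherapies + continuation of the current regimen) yields a
CounterfactualPanel per visit.

The search is exact (full scan) — pools are desk-scale and exactness is
part of the contract.  Distance ties break by ascending visit id, and a
query's own patient is never admitted to its neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import FeatureSchema, modeling_table, regimen_set
from .regression import FittedRegressor
from .synthetic import CURRENT_OPTION, DRUG_CLASSES, NO_REGIMEN

#: pool key for untreated visits (the "current" option of drug-naive visits)
UNTREATED = "none"


def weighted_distance(x: np.ndarray, z: np.ndarray, beta: np.ndarray) -> float:
    """Coefficient-weighted Euclidean distance between two feature vectors."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (x.shape == z.shape == beta.shape):
        raise ValueError(
            f"length mismatch: x{x.shape}, z{z.shape}, beta{beta.shape}"
        )
    d = x - z
    return float(np.sqrt(np.sum(d * d * beta * beta)))


@dataclass
class NeighborPool:
    """Training visits eligible as neighbors for one menu option."""

    key: str
    X: np.ndarray  # (n, p) standardized features
    y: np.ndarray  # (n,) observed future SBP
    visit_ids: np.ndarray
    patient_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class CounterfactualPanel:
    """Predicted next-period SBP for every menu option of one visit.

    ``predictions`` always carries the 7 monotherapy classes (where pools
    exist) plus the key ``"current"``.  When the visit is already on a
    monotherapy from the menu, the current option coincides with that class
    (``current_alias`` names it and the two entries are identical), so the
    effective menu size is 7; otherwise (combo or untreated regimen) the
    current option is distinct and the menu has 8 entries.
    """

    visit_id: int
    regimen: str
    predictions: dict[str, float] = field(default_factory=dict)
    neighbor_ids: dict[str, np.ndarray] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    current_alias: Optional[str] = None

    def options(self) -> list[str]:
        """Deduplicated menu: class labels, plus "current" only when distinct."""
        opts = [c for c in self.predictions if c != CURRENT_OPTION]
        if self.current_alias is None and CURRENT_OPTION in self.predictions:
            opts.append(CURRENT_OPTION)
        return opts

    @property
    def menu_size(self) -> int:
        return len(self.options())


def knn_predict(
    x: np.ndarray,
    pool: NeighborPool,
    beta: np.ndarray,
    k: int,
    exclude_patient: Optional[int] = None,
) -> tuple[float, np.ndarray, bool]:
    """Neighbor-average prediction for one query against one pool.

    Returns ``(y_hat, neighbor visit ids, short_pool_flag)``; the flag is
    set when fewer than ``k`` eligible neighbors exist and all are used.
    Raises on an empty pool, naming it.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(pool) == 0:
        raise ValueError(f"empty neighbor pool for option {pool.key!r}")
    x = np.asarray(x, dtype=float)
    w = np.asarray(beta, dtype=float) ** 2
    diff = pool.X - x
    d2 = (diff * diff) @ w
    if exclude_patient is not None:
        d2 = np.where(pool.patient_ids == exclude_patient, np.inf, d2)
    eligible = int(np.sum(np.isfinite(d2)))
    if eligible == 0:
        raise ValueError(
            f"pool {pool.key!r} has no eligible neighbors after patient exclusion"
        )
    order = np.lexsort((pool.visit_ids, d2))  # ties break by ascending visit id
    take = min(k, eligible)
    idx = order[:take]
    return float(pool.y[idx].mean()), pool.visit_ids[idx].copy(), take < k


def build_pools(
    train_visits: pd.DataFrame,
    schema: FeatureSchema,
    drug_classes=DRUG_CLASSES,
) -> dict[str, NeighborPool]:
    """Index the training visits into per-option neighbor pools.

    Per-class pools contain every visit whose regimen *includes* the class
    (combination regimens count toward each constituent, matching how the
    per-class sub-models are trained); exact-regimen pools (keyed by the
    regimen string) and the untreated pool serve the current-regimen option.
    """
    train = modeling_table(train_visits)
    X = schema.transform(train)
    y = train["future_sbp"].to_numpy(dtype=float)
    vids = train["visit_id"].to_numpy()
    pids = train["patient_id"].to_numpy()
    regimens = train["regimen"].fillna(NO_REGIMEN).to_numpy()

    pools: dict[str, NeighborPool] = {}

    def add(key, mask):
        if mask.any():
            pools[key] = NeighborPool(
                key=key, X=X[mask], y=y[mask], visit_ids=vids[mask], patient_ids=pids[mask]
            )

    member = {c: np.array([c in regimen_set(r) for r in regimens]) for c in drug_classes}
    for c in drug_classes:
        add(c, member[c])
    add(UNTREATED, regimens == NO_REGIMEN)
    for reg in pd.unique(regimens):
        if reg != NO_REGIMEN and "+" in reg:
            add(f"regimen:{reg}", regimens == reg)
    return pools


def _current_beta(regimen: str, models: dict[str, FittedRegressor]) -> np.ndarray:
    """Metric weights for the current-regimen option: the class model's beta
    for a monotherapy, the mean of constituent betas for a combination, and
    the untreated-pool model's beta for a drug-naive visit."""
    classes = sorted(regimen_set(regimen))
    if not classes:
        if UNTREATED in models:
            return models[UNTREATED].coef_
        avail = [m.coef_ for m in models.values()]
    else:
        avail = [models[c].coef_ for c in classes if c in models]
        if not avail:
            avail = [m.coef_ for m in models.values()]
    return np.mean(avail, axis=0)


def build_panel(
    x: np.ndarray,
    visit_id: int,
    patient_id: int,
    regimen: str,
    models: dict[str, FittedRegressor],
    pools: dict[str, NeighborPool],
    k: int,
    drug_classes=DRUG_CLASSES,
) -> CounterfactualPanel:
    """Assemble the full menu of counterfactual predictions for one visit."""
    panel = CounterfactualPanel(visit_id=visit_id, regimen=regimen)
    for c in drug_classes:
        if c not in pools or c not in models:
            panel.flags[c] = "empty_pool"
            continue
        yhat, ids, short = knn_predict(
            x, pools[c], models[c].coef_, k, exclude_patient=patient_id
        )
        panel.predictions[c] = yhat
        panel.neighbor_ids[c] = ids
        if short:
            panel.flags[c] = "short_pool"

    classes = sorted(regimen_set(regimen))
    if len(classes) == 1 and classes[0] in panel.predictions:
        # monotherapy: current option coincides with its class (menu size 7)
        panel.current_alias = classes[0]
        panel.predictions[CURRENT_OPTION] = panel.predictions[classes[0]]
        panel.neighbor_ids[CURRENT_OPTION] = panel.neighbor_ids[classes[0]]
    else:
        beta = _current_beta(regimen, models)
        if not classes:
            pool = pools.get(UNTREATED)
            fallback = None
        else:
            pool = pools.get(f"regimen:{regimen}")
            fallback = classes
        if pool is not None and len(pool) >= k:
            yhat, ids, short = knn_predict(x, pool, beta, k, exclude_patient=patient_id)
        elif fallback:
            # rare combination: fall back to the union of constituent pools
            parts = [pools[c] for c in fallback if c in pools]
            if not parts:
                panel.flags[CURRENT_OPTION] = "empty_pool"
                return panel
            union_vids = np.concatenate([p.visit_ids for p in parts])
            _, uniq = np.unique(union_vids, return_index=True)
            union = NeighborPool(
                key=f"union:{regimen}",
                X=np.concatenate([p.X for p in parts])[uniq],
                y=np.concatenate([p.y for p in parts])[uniq],
                visit_ids=union_vids[uniq],
                patient_ids=np.concatenate([p.patient_ids for p in parts])[uniq],
            )
            yhat, ids, short = knn_predict(x, union, beta, k, exclude_patient=patient_id)
            panel.flags[CURRENT_OPTION] = "combo_fallback"
        elif pool is not None and len(pool) > 0:
            yhat, ids, short = knn_predict(x, pool, beta, k, exclude_patient=patient_id)
            panel.flags[CURRENT_OPTION] = "short_pool"
        else:
            panel.flags[CURRENT_OPTION] = "empty_pool"
            return panel
        panel.predictions[CURRENT_OPTION] = yhat
        panel.neighbor_ids[CURRENT_OPTION] = ids
    return panel


def build_panels(
    visits: pd.DataFrame,
    schema: FeatureSchema,
    models: dict[str, FittedRegressor],
    pools: dict[str, NeighborPool],
    k: int = 50,
    drug_classes=DRUG_CLASSES,
) -> list[CounterfactualPanel]:
    """Panels for every visit in a table (vectorized standardization)."""
    X = schema.transform(visits)
    out = []
    for i, row in enumerate(visits.itertuples()):
        reg = row.regimen if isinstance(row.regimen, str) else NO_REGIMEN
        out.append(
            build_panel(
                X[i], int(row.visit_id), int(row.patient_id), reg,
                models, pools, k, drug_classes=drug_classes,
            )
        )
    return out


def panels_frame(panels: list[CounterfactualPanel]) -> pd.DataFrame:
    """Flat (visit, option) table of predictions — the exchange format."""
    rows = [
        {
            "visit_id": p.visit_id,
            "option": opt,
            "y_hat": yhat,
            "n_neighbors": len(p.neighbor_ids.get(opt, ())),
            "flag": p.flags.get(opt, ""),
        }
        for p in panels
        for opt, yhat in p.predictions.items()
    ]
    return pd.DataFrame(rows)
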