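"""Rule-constrained prescription policy over a counterfactual panel.

Given the menu of predicted next-period SBP values, the policy first
removes options that violate hard clinical contraindication rules, then
either picks the predicted-SBP argmin (deterministic mode) or draws from a
softmax that favors lower predicted SBP (randomized mode),

    p_m  proportional to  w_m * exp(-xi * y_hat_m)

over the allowed options, where xi is an inverse-temperature and w_m >= 1
boosts options flagged by advisory ("should likely") rules.  A switch away
from the current regimen is only adopted when the predicted improvement
exceeds the threshold delta; otherwise the current prescription is kept.

Hard rules (contraindications):
    pulse < 60            -> no Beta-Blocker
    potassium > 4.5       -> no ACEi, no ARB
    creatinine >= 2       -> no ACEi, no ARB, no Thiazide
    potassium > 5         -> no MRA
Advisory rules (preferences, multiplicative boost only):
    diabetes              -> prefer ACEi / ARB
    systolic heart failure-> prefer Beta-Blocker
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .cohort import regimen_set
from .neighbors import CounterfactualPanel
from .synthetic import CURRENT_OPTION

# (rule id, lab/flag column, predicate, excluded classes)
HARD_RULES = (
    ("low_pulse", "pulse", lambda v: v < 60, frozenset({"BetaBlocker"})),
    ("hyperkalemia_mild", "potassium", lambda v: v > 4.5, frozenset({"ACEi", "ARB"})),
    ("renal_impairment", "creatinine", lambda v: v >= 2, frozenset({"ACEi", "ARB", "Thiazide"})),
    ("hyperkalemia_severe", "potassium", lambda v: v > 5, frozenset({"MRA"})),
)
SOFT_RULES = (
    ("diabetes_prefers_raas", "diabetes", frozenset({"ACEi", "ARB"})),
    ("hf_prefers_beta_blocker", "systolic_hf", frozenset({"BetaBlocker"})),
)


class PolicyConfig(BaseModel):
    """Tunables of the prescription policy."""

    xi: float = Field(default=0.5, ge=0.0)  # inverse temperature, 1/mmHg
    delta: float = Field(default=0.0, ge=0.0)  # switch threshold, mmHg
    mode: str = Field(default="randomized", pattern="^(randomized|deterministic)$")
    soft_preference_weight: float = Field(default=1.5, ge=1.0)
    seed: int = 0


@dataclass
class Recommendation:
    """The policy's output for one visit."""

    visit_id: int
    probabilities: dict[str, float]
    chosen: str
    excluded: dict[str, list[str]]  # option -> triggering rule ids
    kept_current: bool
    soft_flags: dict[str, list[str]] = field(default_factory=dict)
    unevaluable_rules: list[str] = field(default_factory=list)
    status: str = "ok"


def _classes_of(option: str, regimen: str) -> frozenset[str]:
    return regimen_set(regimen) if option == CURRENT_OPTION else frozenset({option})


def apply_rules(
    visit: dict, options: list[str], regimen: str = ""
) -> tuple[list[str], dict[str, list[str]], dict[str, list[str]], list[str]]:
    """Filter a menu through the clinical rules.

    ``visit`` maps lab/flag names (pulse, potassium, creatinine, diabetes,
    systolic_hf) to values; missing or NaN labs leave the rule untriggered
    and are reported in the unevaluable list.  The current-regimen option is
    excluded when any of its constituent classes is.  Returns
    (allowed, exclusions, soft flags, unevaluable rule ids).
    """
    excluded_classes: dict[str, list[str]] = {}
    unevaluable: list[str] = []
    for rule_id, col, predicate, targets in HARD_RULES:
        val = visit.get(col)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            unevaluable.append(rule_id)
            continue
        if predicate(val):
            for c in targets:
                excluded_classes.setdefault(c, []).append(rule_id)

    exclusions: dict[str, list[str]] = {}
    allowed: list[str] = []
    for opt in options:
        hits = sorted(
            {r for c in _classes_of(opt, regimen) for r in excluded_classes.get(c, [])}
        )
        if hits:
            exclusions[opt] = hits
        else:
            allowed.append(opt)

    soft_flags: dict[str, list[str]] = {}
    for rule_id, col, targets in SOFT_RULES:
        val = visit.get(col)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            unevaluable.append(rule_id)
            continue
        if val:
            for opt in options:
                if _classes_of(opt, regimen) & targets:
                    soft_flags.setdefault(opt, []).append(rule_id)
    return allowed, exclusions, soft_flags, unevaluable


def softmax_policy(
    predictions: dict[str, float],
    xi: float,
    allowed: list[str],
    soft_flags: Optional[dict[str, list[str]]] = None,
    soft_weight: float = 1.0,
) -> dict[str, float]:
    """Boosted softmax over allowed options; excluded options get exactly 0.

    Probabilities are computed with a max-shift so large xi stays stable,
    and are invariant to adding a constant to every prediction.
    """
    if xi < 0:
        raise ValueError(f"xi must be >= 0, got {xi}")
    if not allowed:
        raise ValueError("allowed option set is empty")
    soft_flags = soft_flags or {}
    yhat = np.array([predictions[m] for m in allowed], dtype=float)
    w = np.array([soft_weight if soft_flags.get(m) else 1.0 for m in allowed])
    logits = -xi * (yhat - yhat.min())
    expo = w * np.exp(logits)
    p = expo / expo.sum()
    probs = {m: 0.0 for m in predictions}
    probs.update(dict(zip(allowed, (float(v) for v in p))))
    return probs


def decide(
    panel: CounterfactualPanel,
    visit: dict,
    config: PolicyConfig,
    rng: Optional[np.random.Generator] = None,
) -> Recommendation:
    """Turn one counterfactual panel into a Recommendation.

    The candidate is the argmin-predicted-SBP option (deterministic) or a
    seeded softmax draw (randomized); it replaces the current regimen only
    when the predicted improvement reaches the switch threshold delta.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    options = panel.options()
    current_label = panel.current_alias or CURRENT_OPTION
    allowed, exclusions, soft_flags, unevaluable = apply_rules(
        visit, options, panel.regimen
    )
    status = "ok"
    if not allowed:
        # every option contraindicated: fall back to the current regimen
        allowed = [current_label] if current_label in options else options[:1]
        status = "all_options_excluded"

    probs = softmax_policy(
        {m: panel.predictions[m] for m in options},
        config.xi, allowed, soft_flags, config.soft_preference_weight,
    )
    if config.mode == "deterministic":
        candidate = min(allowed, key=lambda m: (panel.predictions[m], options.index(m)))
    else:
        labels = list(allowed)
        weights = np.array([probs[m] for m in labels])
        candidate = labels[int(rng.choice(len(labels), p=weights / weights.sum()))]

    chosen = candidate
    kept_current = False
    y_current = panel.predictions.get(CURRENT_OPTION)
    current_allowed = current_label in allowed
    if y_current is not None and candidate != current_label and current_allowed:
        if y_current - panel.predictions[candidate] < config.delta:
            chosen = current_label
            kept_current = True
    if chosen == current_label:
        kept_current = True

    return Recommendation(
        visit_id=panel.visit_id,
        probabilities=probs,
        chosen=chosen,
        excluded=exclusions,
        kept_current=kept_current,
        soft_flags=soft_flags,
        unevaluable_rules=sorted(set(unevaluable)),
        status=status,
    )


def recommend_all(
    panels: list[CounterfactualPanel],
    visits: pd.DataFrame,
    config: PolicyConfig,
) -> list[Recommendation]:
    """Recommendations for a whole visit table (one shared seeded stream)."""
    rng = np.random.default_rng(config.seed)
    byid = visits.set_index("visit_id")
    cols = ["pulse", "potassium", "creatinine", "diabetes", "systolic_hf"]
    out = []
    for p in panels:
        if not p.predictions:
            continue
        row = byid.loc[p.visit_id]
        visit = {c: (float(row[c]) if pd.notna(row[c]) else float("nan")) for c in cols}
        out.append(decide(p, visit, config, rng=rng))
    return out


def tune_xi(
    panels: list[CounterfactualPanel],
    visits: pd.DataFrame,
    config: PolicyConfig,
    target_gap: float = 1.0,
    grid=(0.125, 0.25, 0.5, 1.0, 2.0, 4.0),
) -> float:
    """Smallest xi whose randomized policy matches the deterministic one.

    Chooses the smallest grid value for which the expected predicted SBP
    under the softmax is within ``target_gap`` mmHg (mean over visits) of
    the deterministic argmin's — retaining as much exploration as the
    performance constraint permits.
    """
    byid = visits.set_index("visit_id")
    cols = ["pulse", "potassium", "creatinine", "diabetes", "systolic_hf"]
    prepared = []
    for p in panels:
        if not p.predictions:
            continue
        row = byid.loc[p.visit_id]
        visit = {c: (float(row[c]) if pd.notna(row[c]) else float("nan")) for c in cols}
        allowed, _, soft, _ = apply_rules(visit, p.options(), p.regimen)
        if allowed:
            prepared.append((p, allowed, soft))
    for xi in grid:
        gaps = []
        for p, allowed, soft in prepared:
            probs = softmax_policy(
                {m: p.predictions[m] for m in p.options()},
                xi, allowed, soft, config.soft_preference_weight,
            )
            expected = sum(probs[m] * p.predictions[m] for m in allowed)
            best = min(p.predictions[m] for m in allowed)
            gaps.append(expected - best)
        if np.mean(gaps) <= target_gap:
            return xi
    return grid[-1]
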