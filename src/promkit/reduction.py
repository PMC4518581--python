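"""Staged item-deletion algorithm.

Items pass through five stages in a fixed order; the first rule an item
trips is the one reported for it:

1. fewer than ``min_categories_used`` distinct response options observed;
2. missing fraction strictly greater than ``max_missing_fraction``;
3. floor or ceiling fraction strictly greater than
   ``max_floor_ceiling_fraction`` (retained-but-flagged when the item is in
   ``retain_overrides``);
4. inter-item Pearson correlation strictly greater than ``redundancy_r``
   among survivors (one member of each offending pair is dropped);
5. user-supplied conceptual deletions.

All boundaries are strict inequalities: an item sitting exactly at a
threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnalysisConfig, InstrumentDefinition, ResponseMatrix

RULES = ("categories_used", "missingness", "floor", "ceiling",
         "redundancy", "conceptual", "none")


def categories_used(responses: np.ndarray) -> int:
    """Number of distinct non-missing response options observed."""
    v = np.asarray(responses, dtype=float)
    return int(np.unique(v[~np.isnan(v)]).size)


def missing_fraction(responses: np.ndarray) -> float:
    v = np.asarray(responses, dtype=float)
    if v.size == 0:
        raise ValueError("empty response vector")
    return float(np.isnan(v).mean())


def floor_ceiling_fraction(responses: np.ndarray,
                           floor_value: int = 1,
                           ceiling_value: int = 6) -> tuple[float, float]:
    """Fractions of non-missing responses at the floor (1) and ceiling (6)."""
    v = np.asarray(responses, dtype=float)
    obs = v[~np.isnan(v)]
    if obs.size == 0:
        raise ValueError("all responses missing")
    return float((obs == floor_value).mean()), float((obs == ceiling_value).mean())


def pairwise_item_correlations(matrix: ResponseMatrix,
                               items: list[str]) -> tuple[pd.DataFrame, dict]:
    """Pearson correlations on pairwise-complete observations.

    Returns (correlation frame, reasons) where pairs with fewer than 3
    complete observations or a zero-variance member get NaN and an entry in
    ``reasons`` keyed by the frozenset of the pair.
    """
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    r = pd.DataFrame(np.eye(len(items)), index=items, columns=items)
    reasons: dict[frozenset, str] = {}
    data = {i: matrix.item(i) for i in items}
    for a_idx, a in enumerate(items):
        for b in items[a_idx + 1:]:
            x, y = data[a], data[b]
            ok = ~np.isnan(x) & ~np.isnan(y)
            key = frozenset((a, b))
            if ok.sum() < 3:
                r.loc[a, b] = r.loc[b, a] = np.nan
                reasons[key] = "fewer than 3 complete observations"
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                reasons[key] = "zero variance"
                continue
            r.loc[a, b] = r.loc[b, a] = float(np.corrcoef(xs, ys)[0, 1])
    return r, reasons


@dataclass
class ItemDecision:
    item: str
    status: str                 # retained | deleted | flagged_retained
    rule: str                   # one of RULES
    statistic: float | int | None
    stage: int                  # 0 for untouched survivors
    partner: str | None = None  # redundancy only


@dataclass
class DeletionReport:
    decisions: dict[str, ItemDecision]
    log: list[str] = field(default_factory=list)

    def retained_ids(self) -> list[str]:
        return [i for i, d in self.decisions.items() if d.status != "deleted"]

    def deleted_ids(self) -> list[str]:
        return [i for i, d in self.decisions.items() if d.status == "deleted"]

    def flagged_ids(self) -> list[str]:
        return [i for i, d in self.decisions.items()
                if d.status == "flagged_retained"]

    def rule_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.decisions.values():
            if d.status == "deleted":
                out[d.rule] = out.get(d.rule, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"item": d.item, "status": d.status, "rule": d.rule,
             "statistic": d.statistic, "stage": d.stage, "partner": d.partner}
            for d in self.decisions.values()
        ])


def run_deletion_algorithm(matrix: ResponseMatrix,
                           instrument: InstrumentDefinition,
                           config: AnalysisConfig) -> DeletionReport:
    """Apply the five deletion stages in order and log every decision."""
    ids = instrument.item_ids
    for ov in config.retain_overrides:
        if ov not in ids:
            raise ValueError(f"configured item {ov!r} not in instrument")
    # conceptual ids may reference items already removed by an earlier run
    conceptual = [i for i in config.conceptual_deletions if i in ids]
    decisions = {i: ItemDecision(i, "retained", "none", None, 0) for i in ids}
    log: list[str] = []

    def alive() -> list[str]:
        return [i for i in ids if decisions[i].status != "deleted"]

    # stage 1: category usage
    for i in ids:
        c = categories_used(matrix.item(i))
        if c < config.min_categories_used:
            decisions[i] = ItemDecision(i, "deleted", "categories_used", c, 1)
            log.append(f"stage 1: {i} deleted ({c} categories used)")

    # stage 2: missingness
    for i in alive():
        f = missing_fraction(matrix.item(i))
        if f > config.max_missing_fraction:
            decisions[i] = ItemDecision(i, "deleted", "missingness", f, 2)
            log.append(f"stage 2: {i} deleted ({f:.0%} missing)")

    # stage 3: floor / ceiling
    for i in alive():
        fl, ce = floor_ceiling_fraction(matrix.item(i))
        rule = "floor" if fl > config.max_floor_ceiling_fraction else (
            "ceiling" if ce > config.max_floor_ceiling_fraction else None)
        if rule is None:
            continue
        stat = fl if rule == "floor" else ce
        if i in config.retain_overrides:
            decisions[i] = ItemDecision(i, "flagged_retained", rule, stat, 3)
            log.append(f"stage 3: {i} flagged but retained ({rule} {stat:.0%})")
        else:
            decisions[i] = ItemDecision(i, "deleted", rule, stat, 3)
            log.append(f"stage 3: {i} deleted ({rule} {stat:.0%})")

    # stage 4: redundancy, pairs processed in descending |r|
    survivors = alive()
    if len(survivors) >= 2:
        r, _ = pairwise_item_correlations(matrix, survivors)
        pairs = []
        for a_idx, a in enumerate(survivors):
            for b in survivors[a_idx + 1:]:
                val = r.loc[a, b]
                if np.isfinite(val) and val > config.redundancy_r:
                    pairs.append((float(val), a, b))
        pairs.sort(key=lambda t: -abs(t[0]))
        for val, a, b in pairs:
            if decisions[a].status == "deleted" or decisions[b].status == "deleted":
                continue  # an already-deleted item cannot trigger deletions
            victim, partner = _redundancy_victim(matrix, instrument, a, b)
            decisions[victim] = ItemDecision(victim, "deleted", "redundancy",
                                             val, 4, partner=partner)
            log.append(f"stage 4: {victim} deleted (r={val:.2f} with {partner})")

    # stage 5: conceptual deletions
    for i in conceptual:
        if decisions[i].status != "deleted":
            decisions[i] = ItemDecision(i, "deleted", "conceptual", None, 5)
            log.append(f"stage 5: {i} deleted (conceptual)")

    return DeletionReport(decisions, log)


def _redundancy_victim(matrix, instrument, a, b) -> tuple[str, str]:
    """Tie-break: drop the worse-measured member of a redundant pair.

    Higher missing fraction loses; then higher floor fraction; then the
    later instrument position.  Deterministic by construction.
    """
    ma, mb = missing_fraction(matrix.item(a)), missing_fraction(matrix.item(b))
    if ma != mb:
        return (a, b) if ma > mb else (b, a)
    fa, _ = floor_ceiling_fraction(matrix.item(a))
    fb, _ = floor_ceiling_fraction(matrix.item(b))
    if fa != fb:
        return (a, b) if fa > fb else (b, a)
    order = instrument.item_ids
    return (a, b) if order.index(a) > order.index(b) else (b, a)
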