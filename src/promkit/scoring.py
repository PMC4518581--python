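"""Summation scoring, reliability, and validity analyses.

Scales are scored by summing item responses; when some items of a scale
are missing, the missing responses are imputed with the unrounded mean of
the respondent's answered items in that scale, provided at least half the
items were answered ("at least half" is inclusive: exactly half qualifies).
Respondents below that fraction receive a missing score.  A scale of k
items therefore has possible range [k, 6k]; higher scores connote greater
impairment.

Reliability (Cronbach's alpha) is computed on respondents complete for the
scale — imputation is a scoring convenience, not a measurement model.
Validity analyses cover external-measure correlations (restricted to a
spirometry window), tertile contrasts of an external severity measure
(one-way ANOVA plus a lowest-vs-highest two-sample contrast), and
known-groups comparisons (pooled-variance t-tests with effect sizes in
standard-deviation units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (RESPONSE_MAX, RESPONSE_MIN, AnalysisConfig,
                   InstrumentDefinition, ResponseMatrix)


def score_scale(matrix: ResponseMatrix, items: list[str],
                config: AnalysisConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Summation score with the mean-imputation rule.

    Returns (scores, imputed) where ``scores`` is float with NaN for
    respondents answering less than ``imputation_min_fraction`` of the
    scale, and ``imputed`` flags respondents whose score used imputation.
    """
    if not items:
        raise ValueError("empty item list")
    config = config or AnalysisConfig()
    vals = matrix.responses[list(items)].to_numpy()
    k = len(items)
    answered = (~np.isnan(vals)).sum(axis=1)
    frac = answered / k
    sums = np.nansum(vals, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_answered = sums / answered
    total = sums + mean_answered * (k - answered)
    ok = frac >= config.imputation_min_fraction
    scores = np.where(ok, total, np.nan)
    imputed = ok & (answered < k)
    return scores, imputed


def scale_range(items: list[str]) -> tuple[int, int]:
    """Possible range of a k-item summated scale: [k, 6k]."""
    k = len(items)
    return k * RESPONSE_MIN, k * RESPONSE_MAX


@dataclass
class ScoreSet:
    """Domain scores plus the total score over all final items."""

    domain_scores: pd.DataFrame          # n x domains (NaN = unscorable)
    total: np.ndarray
    imputed: pd.DataFrame                # bool flags, domains + "total"
    ranges: dict[str, tuple[int, int]]   # scale -> (min possible, max possible)
    scales: dict[str, list[str]]         # scale -> item ids

    def score(self, scale: str) -> np.ndarray:
        if scale == "total":
            return self.total
        return self.domain_scores[scale].to_numpy()

    @property
    def scale_names(self) -> list[str]:
        return list(self.domain_scores.columns) + ["total"]


def score_set(matrix: ResponseMatrix, instrument: InstrumentDefinition,
              config: AnalysisConfig | None = None) -> ScoreSet:
    """Score every domain and the total (all items, standalone included).

    The total is the sum over all final items with the imputation rule
    applied at the total level — not the sum of domain scores.
    """
    config = config or AnalysisConfig()
    dom_scores, imputed, ranges, scales = {}, {}, {}, {}
    for d in instrument.domains:
        ids = instrument.domain_items(d)
        if not ids:
            continue
        s, f = score_scale(matrix, ids, config)
        dom_scores[d], imputed[d] = s, f
        ranges[d] = scale_range(ids)
        scales[d] = ids
    all_items = instrument.item_ids
    tot, tot_f = score_scale(matrix, all_items, config)
    imputed["total"] = tot_f
    ranges["total"] = scale_range(all_items)
    scales["total"] = all_items
    return ScoreSet(
        domain_scores=pd.DataFrame(dom_scores),
        total=tot,
        imputed=pd.DataFrame(imputed),
        ranges=ranges,
        scales=scales,
    )


def cronbach_alpha(matrix: ResponseMatrix, items: list[str]
                   ) -> tuple[float, float]:
    """Cronbach's alpha and mean inter-item correlation (complete cases).

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total),
    with sample (ddof=1) variances over respondents answering every item.
    """
    k = len(items)
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    vals = matrix.responses[list(items)].to_numpy()
    complete = ~np.isnan(vals).any(axis=1)
    if complete.sum() < 3:
        raise ValueError("alpha requires at least 3 complete respondents")
    v = vals[complete]
    total_var = v.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    item_vars = v.var(axis=0, ddof=1)
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    c = np.corrcoef(v, rowvar=False)
    iu = np.triu_indices(k, 1)
    mean_r = float(np.mean(c[iu]))
    return float(alpha), mean_r


def floor_ceiling_scale(scores: np.ndarray,
                        possible_range: tuple[float, float]
                        ) -> tuple[float, float]:
    """Percent of non-missing scores exactly at the possible min / max."""
    s = np.asarray(scores, dtype=float)
    obs = s[~np.isnan(s)]
    if obs.size == 0:
        raise ValueError("all scores missing")
    lo, hi = possible_range
    return 100.0 * float((obs == lo).mean()), 100.0 * float((obs == hi).mean())


def reliability_report(matrix: ResponseMatrix,
                       instrument: InstrumentDefinition,
                       config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-scale summary: alpha, items, mean inter-item r, ranges,
    mean +/- sd, % floor, % ceiling, n used."""
    config = config or AnalysisConfig()
    ss = score_set(matrix, instrument, config)
    rows = []
    for scale in ss.scale_names:
        items = ss.scales[scale]
        s = ss.score(scale)
        obs = s[~np.isnan(s)]
        lo, hi = ss.ranges[scale]
        try:
            alpha, mean_r = cronbach_alpha(matrix, items)
        except ValueError:
            alpha, mean_r = np.nan, np.nan
        fl, ce = floor_ceiling_scale(s, (lo, hi))
        rows.append({
            "scale": scale, "alpha": alpha, "items": len(items),
            "mean_interitem_r": mean_r,
            "range_possible": f"{lo}-{hi}",
            "range_used": f"{obs.min():g}-{obs.max():g}" if obs.size else "",
            "mean": obs.mean() if obs.size else np.nan,
            "sd": obs.std(ddof=1) if obs.size > 1 else np.nan,
            "pct_floor": fl, "pct_ceiling": ce, "n": int(obs.size),
        })
    return pd.DataFrame(rows)


def external_correlations(scores: ScoreSet, matrix: ResponseMatrix,
                          config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Pearson r of each scale with the external severity measure.

    Restricted to respondents with |spiro_window_days| <= the configured
    maximum.  Scales with fewer than 4 usable respondents or zero variance
    are marked not estimable.
    """
    config = config or AnalysisConfig()
    sev = matrix.covariate("severity_pct").astype(float)
    window = matrix.covariate("spiro_window_days").astype(float)
    usable = ~np.isnan(sev) & (np.abs(window) <= config.spiro_window_days_max)
    rows = []
    for scale in scores.scale_names:
        s = scores.score(scale)
        ok = usable & ~np.isnan(s)
        n = int(ok.sum())
        if n < 4 or np.std(s[ok]) == 0 or np.std(sev[ok]) == 0:
            rows.append({"scale": scale, "r": np.nan, "p": np.nan,
                         "n": n, "estimable": False})
            continue
        r, p = stats.pearsonr(s[ok], sev[ok])
        rows.append({"scale": scale, "r": float(r), "p": float(p),
                     "n": n, "estimable": True})
    return pd.DataFrame(rows)


@dataclass
class TertileReport:
    cuts: tuple[float, float]
    group_n: list[int]
    group_mean: list[float]
    group_se: list[float]
    f_stat: float
    f_p: float
    contrast_t: float           # lowest vs highest tertile
    contrast_p: float


def tertile_groups(severity: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Tertile labels 0/1/2 by interpolated sample terciles.

    Boundary values are assigned to the lower tertile.
    """
    sev = np.asarray(severity, dtype=float)
    q1, q2 = np.quantile(sev, [1 / 3, 2 / 3])
    g = np.where(sev <= q1, 0, np.where(sev <= q2, 1, 2))
    return g, (float(q1), float(q2))


def tertile_contrast(scores: np.ndarray, severity: np.ndarray) -> TertileReport:
    """One-way ANOVA over severity tertiles plus lowest-vs-highest t-test."""
    s = np.asarray(scores, dtype=float)
    sev = np.asarray(severity, dtype=float)
    ok = ~np.isnan(s) & ~np.isnan(sev)
    if ok.sum() < 6:
        raise ValueError("need at least 6 usable respondents")
    s, sev = s[ok], sev[ok]
    g, cuts = tertile_groups(sev)
    groups = [s[g == k] for k in range(3)]
    if any(len(gr) == 0 for gr in groups):
        raise ValueError(f"tied severity values leave an empty tertile "
                         f"(cut points {cuts})")
    f, p = stats.f_oneway(*groups)
    t, tp = stats.ttest_ind(groups[0], groups[2], equal_var=True)
    return TertileReport(
        cuts=cuts,
        group_n=[len(gr) for gr in groups],
        group_mean=[float(gr.mean()) for gr in groups],
        group_se=[float(gr.std(ddof=1) / np.sqrt(len(gr))) if len(gr) > 1
                  else np.nan for gr in groups],
        f_stat=float(f), f_p=float(p),
        contrast_t=float(t), contrast_p=float(tp),
    )


@dataclass
class GroupReport:
    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]
    difference: float            # mean(group 1) - mean(group 2)
    pooled_sd: float
    sdu: float                   # difference / pooled sd
    t_stat: float
    p: float


def group_comparison(scores: np.ndarray, group: np.ndarray,
                     welch: bool = False) -> GroupReport:
    """Two-group comparison: pooled-variance t-test and SDU effect size.

    ``group`` is boolean (True = first group, e.g. oxygen users).  The
    difference is first-group mean minus second-group mean; SDU divides by
    the pooled standard deviation.  With a group of fewer than 2 members
    the means are still reported but the test is not estimable.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(group, dtype=bool)
    ok = ~np.isnan(s)
    x, y = s[ok & g], s[ok & ~g]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    stats_ = group_comparison_from_summary(
        float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else np.nan, x.size,
        float(y.mean()), float(y.std(ddof=1)) if y.size > 1 else np.nan, y.size,
    )
    if welch and x.size > 1 and y.size > 1:
        t, p = stats.ttest_ind(x, y, equal_var=False)
        stats_ = GroupReport(stats_.n, stats_.mean, stats_.sd,
                             stats_.difference, stats_.pooled_sd, stats_.sdu,
                             float(t), float(p))
    return stats_


def group_comparison_from_summary(m1: float, sd1: float, n1: int,
                                  m2: float, sd2: float, n2: int
                                  ) -> GroupReport:
    """Group comparison from summary statistics alone (means, sds, ns).

    Useful for recomputing derived columns of published tables:
    difference of means, pooled sd, SDU and the pooled-variance t-test.
    """
    diff = m1 - m2
    if n1 > 1 and n2 > 1 and np.isfinite(sd1) and np.isfinite(sd2):
        pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2)
                         / (n1 + n2 - 2))
        if pooled > 0:
            t = diff / (pooled * np.sqrt(1 / n1 + 1 / n2))
            p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
            return GroupReport((n1, n2), (m1, m2), (sd1, sd2), diff,
                               float(pooled), float(diff / pooled),
                               float(t), float(p))
        return GroupReport((n1, n2), (m1, m2), (sd1, sd2), diff,
                           0.0, np.nan, np.nan, np.nan)
    return GroupReport((n1, n2), (m1, m2), (sd1, sd2), diff,
                       np.nan, np.nan, np.nan, np.nan)


def validity_report(matrix: ResponseMatrix, instrument: InstrumentDefinition,
                    config: AnalysisConfig | None = None) -> dict:
    """Assemble the validity analyses for every scale.

    Returns a dict with keys ``external`` (correlation frame), ``tertiles``
    (scale -> TertileReport) and ``oxygen`` (scale -> GroupReport); tertile
    analyses use only respondents inside the spirometry window.
    """
    config = config or AnalysisConfig()
    ss = score_set(matrix, instrument, config)
    out: dict = {"external": external_correlations(ss, matrix, config),
                 "tertiles": {}, "oxygen": {}}
    sev = matrix.covariate("severity_pct").astype(float)
    window = matrix.covariate("spiro_window_days").astype(float)
    in_window = ~np.isnan(sev) & (np.abs(window) <= config.spiro_window_days_max)
    oxy = matrix.covariate("oxygen_use") == "ever"
    for scale in ss.scale_names:
        s = ss.score(scale)
        try:
            out["tertiles"][scale] = tertile_contrast(
                np.where(in_window, s, np.nan), sev)
        except ValueError:
            out["tertiles"][scale] = None
        try:
            out["oxygen"][scale] = group_comparison(s, oxy)
        except ValueError:
            out["oxygen"][scale] = None
    return out
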