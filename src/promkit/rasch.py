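"""Partial Credit Model (PCM) fitting by joint maximum likelihood.

The PCM places persons (measures theta, in logits) and item step
difficulties (delta, in logits) on one scale.  For an item with m steps the
probability of responding in category x in 0..m is

    P(X = x | theta) = exp(sum_{j<=x} (theta - delta_j)) /
                       sum_{h=0..m} exp(sum_{j<=h} (theta - delta_j))

with the empty sum equal to 0.  Each step difficulty delta_j is the logit
at which categories j-1 and j are equally probable (the Andrich
threshold).  Estimation alternates Newton-Raphson updates of person
measures and step difficulties (JMLE), re-centering item difficulties to
mean zero each cycle; this is the identification constraint, so the mean
item difficulty is 0 by construction.

Responses enter this module on the instrument's 1..6 scale and are recoded
internally to 0-based analysis categories, collapsing categories the sample
never used (renumbering preserves order).  Missing responses are simply
omitted from person and item sums; JMLE handles incomplete data natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import InstrumentDefinition, ResponseMatrix

logger = logging.getLogger(__name__)

MISSING = -1  # internal missing code in integer category matrices


def pcm_category_probs(theta: float | np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Category probabilities of the PCM, overflow-safe.

    Parameters
    ----------
    theta:
        scalar or vector of person measures (logits).
    steps:
        step difficulties delta_1..delta_m (logits).

    Returns
    -------
    Probabilities over categories 0..m; shape ``(m+1,)`` for scalar theta,
    ``(n, m+1)`` for vector theta.  Rows sum to 1 exactly up to float error.
    """
    steps = np.asarray(steps, dtype=float)
    if steps.ndim != 1 or steps.size == 0:
        raise ValueError("steps must be a non-empty 1-d vector")
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    h = np.arange(steps.size + 1)
    logits = theta_arr[:, None] * h[None, :] - cum[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if np.isscalar(theta) or np.ndim(theta) == 0 else p


@dataclass
class CodedMatrix:
    """Responses recoded to 0-based categories with collapse bookkeeping."""

    data: np.ndarray                       # (n_persons, n_items) int, MISSING = -1
    person_ids: list
    item_ids: list[str]
    n_steps: np.ndarray                    # per item, number of steps m_i
    collapse_maps: dict[str, dict[int, int]]   # original option -> category
    excluded_persons: list[tuple[object, str]] = field(default_factory=list)
    excluded_items: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]


def collapse_unobserved_categories(matrix: ResponseMatrix,
                                   items: list[str]) -> CodedMatrix:
    """Recode responses to 0..m_i per item, dropping unused categories.

    Unused response options are removed by renumbering the observed options
    in order (a monotone collapse map).  Items with a single used category
    carry no information and are excluded; persons whose every answered
    response sits at an extreme analysis category (all-minimum or
    all-maximum) are likewise excluded from estimation, with reasons
    recorded.  Exclusions can cascade, so the pass repeats to a fixed
    point.
    """
    raw = matrix.responses[list(items)].to_numpy()
    coded = np.where(np.isnan(raw), MISSING, 0).astype(int)
    person_ids = list(matrix.respondent_ids)
    item_keep = list(range(len(items)))
    person_keep = list(range(len(person_ids)))
    excluded_items: list[tuple[str, str]] = []
    excluded_persons: list[tuple[object, str]] = []
    maps: dict[str, dict[int, int]] = {}

    while True:
        changed = False
        sub = raw[np.ix_(person_keep, item_keep)]
        # --- items: collapse and drop single-category items
        new_item_keep = []
        for pos, j in enumerate(item_keep):
            col = sub[:, pos]
            used = np.unique(col[~np.isnan(col)]).astype(int)
            if used.size <= 1:
                excluded_items.append(
                    (items[j], f"only {used.size} used category"))
                changed = True
                continue
            new_item_keep.append(j)
        item_keep = new_item_keep
        sub = raw[np.ix_(person_keep, item_keep)]
        maps = {}
        m = np.zeros(len(item_keep), dtype=int)
        coded_sub = np.full(sub.shape, MISSING, dtype=int)
        for pos, j in enumerate(item_keep):
            col = sub[:, pos]
            used = np.unique(col[~np.isnan(col)]).astype(int)
            cmap = {int(v): k for k, v in enumerate(used)}
            maps[items[j]] = cmap
            m[pos] = used.size - 1
            obs = ~np.isnan(col)
            coded_sub[obs, pos] = [cmap[int(v)] for v in col[obs]]
        # --- persons: flag extremes
        new_person_keep = []
        for pos, i in enumerate(person_keep):
            row = coded_sub[pos]
            obs = row != MISSING
            if not obs.any():
                excluded_persons.append((person_ids[i], "no responses"))
                changed = True
                continue
            if (row[obs] == 0).all():
                excluded_persons.append((person_ids[i], "extreme-minimum"))
                changed = True
                continue
            if (row[obs] == m[obs]).all():
                excluded_persons.append((person_ids[i], "extreme-maximum"))
                changed = True
                continue
            new_person_keep.append(i)
        person_keep = new_person_keep
        if not changed:
            break

    sub = raw[np.ix_(person_keep, item_keep)]
    kept_items = [items[j] for j in item_keep]
    m = np.array([len(maps[i]) - 1 for i in kept_items], dtype=int)
    coded = np.full(sub.shape, MISSING, dtype=int)
    for pos, item_id in enumerate(kept_items):
        col = sub[:, pos]
        obs = ~np.isnan(col)
        coded[obs, pos] = [maps[item_id][int(v)] for v in col[obs]]
    return CodedMatrix(
        data=coded,
        person_ids=[person_ids[i] for i in person_keep],
        item_ids=kept_items,
        n_steps=m,
        collapse_maps=maps,
        excluded_persons=excluded_persons,
        excluded_items=excluded_items,
    )


@dataclass
class FitConfig:
    """JMLE iteration controls."""

    tol: float = 1e-3            # max |parameter change| at convergence, logits
    max_iter: int = 200
    clamp: float = 10.0          # |theta|, |delta| bound during iteration
    extreme_adjust: float = 0.3  # raw-score inward adjustment for extremes
    bias_correction: bool = False  # multiply deltas by (L-1)/L after fit
    track_likelihood: bool = False


@dataclass
class RaschFit:
    """Converged (or partial) PCM solution with fit statistics."""

    item_ids: list[str]
    steps: list[np.ndarray]             # per item, delta_1..delta_m
    item_difficulty: np.ndarray         # mean of each item's steps
    item_infit: np.ndarray
    item_outfit: np.ndarray
    person_ids: list
    theta: np.ndarray
    person_se: np.ndarray
    raw_score: np.ndarray
    person_infit: np.ndarray
    person_outfit: np.ndarray
    converged: bool
    n_iter: int
    max_change: float
    coded: CodedMatrix
    extreme_measures: list[tuple[object, float, str]] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def mean_item_difficulty(self) -> float:
        return float(self.item_difficulty.mean())

    @property
    def mean_person_measure(self) -> float:
        return float(self.theta.mean())

    def item_table(self) -> pd.DataFrame:
        rows = []
        for k, item_id in enumerate(self.item_ids):
            rows.append({
                "item": item_id,
                "difficulty": self.item_difficulty[k],
                "n_steps": len(self.steps[k]),
                "infit": self.item_infit[k],
                "outfit": self.item_outfit[k],
                **{f"step_{j+1}": s for j, s in enumerate(self.steps[k])},
            })
        return pd.DataFrame(rows)

    def person_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "person": self.person_ids,
            "measure": self.theta,
            "se": self.person_se,
            "raw_score": self.raw_score,
            "infit": self.person_infit,
            "outfit": self.person_outfit,
        })


def _prob_tensor(theta: np.ndarray, delta: np.ndarray, m: np.ndarray) -> np.ndarray:
    """P over categories: shape (n_persons, n_items, max_m+1); invalid cats 0."""
    n, I = theta.size, delta.shape[0]
    M = delta.shape[1]
    cum = np.concatenate([np.zeros((I, 1)), np.cumsum(delta, axis=1)], axis=1)
    h = np.arange(M + 1)
    logits = theta[:, None, None] * h[None, None, :] - cum[None, :, :]
    invalid = h[None, :] > m[:, None]           # (I, M+1)
    logits = np.where(invalid[None, :, :], -np.inf, logits)
    logits -= logits.max(axis=2, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=2, keepdims=True)
    return p


def _expected_and_var(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = np.arange(p.shape[2])
    e = (p * h).sum(axis=2)
    v = (p * h**2).sum(axis=2) - e**2
    return e, v


def fit_pcm(coded: CodedMatrix, config: FitConfig | None = None) -> RaschFit:
    """Joint maximum likelihood fit of the PCM.

    Alternates one Newton step on every step difficulty with one Newton step
    on every person measure, re-centering the item difficulties to mean 0
    after each cycle.  Convergence is declared when the largest absolute
    parameter change falls below ``config.tol``; hitting ``max_iter`` first
    is reported as non-convergence with partial results returned.
    """
    config = config or FitConfig()
    X = coded.data
    n, I = X.shape
    if n < 2 or I < 2:
        raise ValueError("need at least 2 non-extreme persons and 2 items")
    _check_connected(X)
    m = coded.n_steps
    M = int(m.max())
    obs = X != MISSING
    Xc = np.where(obs, X, 0)

    raw = (X * obs).sum(axis=1).astype(float)
    max_score = (m[None, :] * obs).sum(axis=1).astype(float)
    # PROX-style starting values
    with np.errstate(divide="ignore"):
        theta = np.log(raw / np.maximum(max_score - raw, 1e-9))
    theta = np.clip(np.nan_to_num(theta), -3, 3)
    delta = np.zeros((I, M))
    delta[np.arange(M)[None, :] >= m[:, None]] = 0.0  # padded, masked later
    step_valid = np.arange(M)[None, :] < m[:, None]

    # observed counts of X >= j per item (j = 1..M)
    ge_obs = np.zeros((I, M))
    for j in range(1, M + 1):
        ge_obs[:, j - 1] = ((X >= j) & obs).sum(axis=0)

    def cell_loglik(th, dl):
        """Per-cell log-likelihood, (n, I); zeros at missing cells."""
        p = _prob_tensor(th, dl, m)
        pi = p[np.arange(n)[:, None], np.arange(I)[None, :], np.clip(X, 0, M)]
        return np.where(obs, np.log(np.maximum(pi, 1e-300)), 0.0)

    def item_sweep(theta, delta):
        """One Newton step on every step difficulty, per-item backtracking
        (item likelihoods are separable given theta)."""
        p = _prob_tensor(theta, delta, m)
        ge_p = p[:, :, ::-1].cumsum(axis=2)[:, :, ::-1]   # P(X >= h)
        ge_p = ge_p[:, :, 1:]                             # h = 1..M
        ge_p = ge_p * obs[:, :, None]
        grad = ge_p.sum(axis=0) - ge_obs
        info = (ge_p * (1.0 - ge_p)).sum(axis=0)
        step = np.where(step_valid & (info > 1e-10),
                        grad / np.maximum(info, 1e-10), 0.0)
        step = np.clip(step, -2.0, 2.0)
        ll_item = cell_loglik(theta, delta).sum(axis=0)
        alpha = np.ones(I)
        accepted = np.zeros(I, dtype=bool)
        new_delta = delta.copy()
        for _ in range(10):
            trial = np.clip(delta + alpha[:, None] * step,
                            -config.clamp, config.clamp)
            ll_try = cell_loglik(theta, trial).sum(axis=0)
            ok = (ll_try >= ll_item - 1e-12) & ~accepted
            new_delta[ok] = trial[ok]
            accepted |= ok
            if accepted.all():
                break
            alpha = np.where(accepted, alpha, alpha * 0.5)
        change = float(np.abs(new_delta - delta)[step_valid].max()) \
            if step_valid.any() else 0.0
        return new_delta, change

    def person_sweep(theta, delta):
        """One Newton step on every person measure, per-person backtracking
        (person likelihoods are separable given delta)."""
        p = _prob_tensor(theta, delta, m)
        e, v = _expected_and_var(p)
        num = raw - (e * obs).sum(axis=1)
        den = np.maximum((v * obs).sum(axis=1), 1e-10)
        pstep = np.clip(num / den, -2.0, 2.0)
        ll_person = cell_loglik(theta, delta).sum(axis=1)
        alpha = np.ones(n)
        accepted = np.zeros(n, dtype=bool)
        new_theta = theta.copy()
        for _ in range(10):
            trial = np.clip(theta + alpha * pstep, -config.clamp, config.clamp)
            ll_try = cell_loglik(trial, delta).sum(axis=1)
            ok = (ll_try >= ll_person - 1e-12) & ~accepted
            new_theta[ok] = trial[ok]
            accepted |= ok
            if accepted.all():
                break
            alpha = np.where(accepted, alpha, alpha * 0.5)
        return new_theta, float(np.abs(new_theta - theta).max())

    loglik_trace: list[float] = []
    max_change = np.inf
    it = 0
    inner_max = 8
    for it in range(1, config.max_iter + 1):
        if config.track_likelihood:
            loglik_trace.append(float(cell_loglik(theta, delta).sum()))
        prev_delta, prev_theta = delta.copy(), theta.copy()
        # inner sweeps fully solve each block before alternating
        for _ in range(inner_max):
            delta, delta_change = item_sweep(theta, delta)
            if delta_change < config.tol / 4:
                break
        # re-center: mean item difficulty (mean of valid steps per item) = 0
        item_diff = np.array([delta[i, :m[i]].mean() for i in range(I)])
        center = item_diff.mean()
        delta[step_valid] -= center
        theta = theta - center
        for _ in range(inner_max):
            theta, theta_change = person_sweep(theta, delta)
            if theta_change < config.tol / 4:
                break
        # convergence judged on the identified (re-centered) scale,
        # cycle over cycle
        max_change = max(
            float(np.abs(delta - prev_delta)[step_valid].max()),
            float(np.abs(theta - prev_theta).max()),
        )
        if max_change < config.tol:
            break
    converged = max_change < config.tol
    if not converged:
        logger.warning("JMLE did not converge in %d iterations (max change %.2g)",
                       config.max_iter, max_change)

    if config.bias_correction and I > 1:
        delta = delta * (I - 1) / I
        item_diff = np.array([delta[i, :m[i]].mean() for i in range(I)])
        delta[step_valid] -= item_diff.mean()

    # person SEs from observed information
    p = _prob_tensor(theta, delta, m)
    e, v = _expected_and_var(p)
    info_person = (v * obs).sum(axis=1)
    person_se = 1.0 / np.sqrt(np.maximum(info_person, 1e-10))

    steps = [delta[i, :m[i]].copy() for i in range(I)]
    item_difficulty = np.array([s.mean() for s in steps])

    item_infit, item_outfit, person_infit, person_outfit = _mnsq(X, obs, e, v)

    extreme_measures = _extreme_person_measures(coded, delta, m, config)

    return RaschFit(
        item_ids=list(coded.item_ids),
        steps=steps,
        item_difficulty=item_difficulty,
        item_infit=item_infit,
        item_outfit=item_outfit,
        person_ids=list(coded.person_ids),
        theta=theta,
        person_se=person_se,
        raw_score=raw,
        person_infit=person_infit,
        person_outfit=person_outfit,
        converged=converged,
        n_iter=it,
        max_change=float(max_change),
        coded=coded,
        extreme_measures=extreme_measures,
        loglik_trace=loglik_trace,
    )


def _check_connected(X: np.ndarray) -> None:
    """Fail on disconnected designs (no response overlap between subsets)."""
    obs = X != MISSING
    n, I = X.shape
    item_comp = -np.ones(I, dtype=int)
    comp = 0
    for start in range(I):
        if item_comp[start] >= 0:
            continue
        stack = [start]
        item_comp[start] = comp
        while stack:
            j = stack.pop()
            persons = np.flatnonzero(obs[:, j])
            linked = np.flatnonzero(obs[persons].any(axis=0))
            for k in linked:
                if item_comp[k] < 0:
                    item_comp[k] = comp
                    stack.append(k)
        comp += 1
    if comp > 1:
        raise ValueError("response design is disconnected; cannot place all "
                         "items on one scale")


def _mnsq(X, obs, e, v):
    resid2 = (np.where(obs, X, 0) - e) ** 2 * obs
    v_safe = np.maximum(v, 1e-10)
    with np.errstate(invalid="ignore"):
        item_infit = resid2.sum(axis=0) / np.maximum((v * obs).sum(axis=0), 1e-10)
        item_outfit = np.array([
            (resid2[obs[:, j], j] / v_safe[obs[:, j], j]).mean()
            if obs[:, j].any() else np.nan
            for j in range(X.shape[1])
        ])
        person_infit = resid2.sum(axis=1) / np.maximum((v * obs).sum(axis=1), 1e-10)
        person_outfit = np.array([
            (resid2[i, obs[i]] / v_safe[i, obs[i]]).mean()
            if obs[i].any() else np.nan
            for i in range(X.shape[0])
        ])
    return item_infit, item_outfit, person_infit, person_outfit


def _extreme_person_measures(coded: CodedMatrix, delta, m, config) -> list:
    """Finite measures for excluded extreme persons via adjusted raw scores."""
    out = []
    adj = config.extreme_adjust
    for pid, reason in coded.excluded_persons:
        if reason == "extreme-minimum":
            target = adj
        elif reason == "extreme-maximum":
            target = float(m.sum()) - adj
        else:
            continue
        # extremes answered every kept item by construction of the flag only
        # when all answered responses are extreme; solve on the full item set
        theta = 0.0
        for _ in range(100):
            p = _prob_tensor(np.array([theta]), delta, m)
            e, v = _expected_and_var(p)
            g = target - e.sum()
            vv = max(v.sum(), 1e-10)
            step = np.clip(g / vv, -2, 2)
            theta = float(np.clip(theta + step, -config.clamp, config.clamp))
            if abs(step) < 1e-6:
                break
        out.append((pid, theta, reason))
    return out


def fit_statistics(coded: CodedMatrix, fit: RaschFit) -> pd.DataFrame:
    """Recompute infit/outfit mean squares from a fit (items and persons).

    infit_i  = sum_n (x_ni - E_ni)^2 / sum_n W_ni   (information-weighted)
    outfit_i = mean_n (x_ni - E_ni)^2 / W_ni        (unweighted)
    """
    X = coded.data
    obs = X != MISSING
    delta = np.full((len(fit.item_ids), int(coded.n_steps.max())), 0.0)
    for i, s in enumerate(fit.steps):
        delta[i, :len(s)] = s
    p = _prob_tensor(fit.theta, delta, coded.n_steps)
    e, v = _expected_and_var(p)
    ii, io, pi_, po = _mnsq(X, obs, e, v)
    items = pd.DataFrame({"id": fit.item_ids, "kind": "item",
                          "infit": ii, "outfit": io})
    persons = pd.DataFrame({"id": fit.person_ids, "kind": "person",
                            "infit": pi_, "outfit": po})
    return pd.concat([items, persons], ignore_index=True)


def classify_fit(infit: float, config=None) -> str:
    """Infit band: useful in [0.5, 1.5], degrading above 2.0, noisy between.

    Values below 0.5 fall outside the useful band and are classified
    noisy_but_usable (overfit direction).
    """
    lo, hi = (0.5, 1.5) if config is None else config.infit_useful
    degrade = 2.0 if config is None else config.infit_degrade
    if infit < 0:
        raise ValueError("infit mean square cannot be negative")
    if lo <= infit <= hi:
        return "useful"
    if infit > degrade:
        return "degrading"
    return "noisy_but_usable"


def wright_map(fit: RaschFit, instrument: InstrumentDefinition | None = None):
    """Person-item map data: thresholds and measures on the common scale.

    Returns (items frame, persons frame, summary dict).  An item coded into
    c analysis categories exports c-1 thresholds.
    """
    rows = []
    for k, item_id in enumerate(fit.item_ids):
        domain = instrument.domain_of(item_id) if instrument is not None else None
        for j, thr in enumerate(fit.steps[k], start=1):
            rows.append({"item": item_id, "domain": domain,
                         "threshold": j, "logit": thr})
    items = pd.DataFrame(rows)
    persons = pd.DataFrame({"person": fit.person_ids, "logit": fit.theta})
    summary = {
        "mean_item_difficulty": fit.mean_item_difficulty,
        "mean_person_measure": fit.mean_person_measure,
    }
    return items, persons, summary


def fit_pcm_from_matrix(matrix: ResponseMatrix, items: list[str],
                        config: FitConfig | None = None) -> RaschFit:
    """Convenience wrapper: collapse categories then fit."""
    coded = collapse_unobserved_categories(matrix, items)
    return fit_pcm(coded, config)
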