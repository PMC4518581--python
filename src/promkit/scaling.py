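"""Multitrait scaling: item-domain correlations, the correlated-correlations
z-test, cell classification and rescaling proposals.

The scaling matrix has one row per domain-assigned item and one column per
domain; each cell holds the Pearson correlation between the item and the
domain's summated score.  With the overlap correction (the default), an
item's own-domain score excludes the item itself, removing the spurious
self-correlation.  An item converges on its domain when its own-domain
correlation reaches the convergent threshold (0.3 by default); it
discriminates when the own-domain correlation significantly exceeds every
competing-domain correlation, tested with the z-test for two dependent
correlations sharing one variable (Meng, Rosenthal & Rubin):

    z = (atanh(r1) - atanh(r2)) * sqrt((N - 3) / (2 (1 - r_yy) h)),
    h = (1 - f rbar^2) / (1 - rbar^2),
    f = min(1, (1 - r_yy) / (2 (1 - rbar^2))),   rbar^2 = (r1^2 + r2^2) / 2

where r1 is the own-domain correlation, r2 the competing one, and r_yy the
correlation between the two domain scores.

Off-diagonal cells are classified: *success* (r1 > r2, significant),
*probable* (r1 > r2, not significant; ties count as probable), *possible*
(r1 < r2, not significant), *failure* (r1 < r2, significant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, InstrumentDefinition, ResponseMatrix
from .scoring import score_scale

CLASSES = ("success", "probable", "possible", "failure", "not_applicable")


@dataclass(frozen=True)
class MengResult:
    """z-test for the difference of two correlations sharing one variable."""

    r1: float
    r2: float
    r_yy: float
    n: int
    z: float
    p: float


def meng_z_test(r1: float, r2: float, r_yy: float, n: int) -> MengResult:
    """Two-sided z-test comparing dependent correlations r1 and r2.

    ``r_yy`` is the correlation between the two variables that are each
    correlated with the shared third variable.  The shrinkage factor f is
    capped at 1 as the method prescribes.  Degenerate inputs (any unit
    correlation, n < 4) raise ValueError.
    """
    if n < 4:
        raise ValueError("Meng z-test requires N >= 4")
    for name, v in (("r1", r1), ("r2", r2)):
        if not -1.0 < v < 1.0:
            raise ValueError(f"{name}={v} must lie strictly inside (-1, 1)")
    if not -1.0 <= r_yy < 1.0:
        raise ValueError(f"r_yy={r_yy} must lie in [-1, 1)")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar2 = (r1**2 + r2**2) / 2.0
    f = min(1.0, (1.0 - r_yy) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r_yy) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return MengResult(r1, r2, r_yy, n, float(z), float(p))


@dataclass
class ScalingMatrix:
    """Item x domain correlations with classifications and test results."""

    items: list[str]                       # domain-assigned items (rows)
    domains: list[str]                     # columns
    own_domain: dict                       # item -> its hypothesized domain
    r: pd.DataFrame                        # correlations (NaN = not applicable)
    n: pd.DataFrame                        # pairwise-complete counts
    corrected: bool
    domain_scores: pd.DataFrame            # uncorrected domain scores
    own_scores: pd.DataFrame               # per item, its own-domain score
    classification: pd.DataFrame | None = None
    z: pd.DataFrame | None = None
    p: pd.DataFrame | None = None
    meng: dict = field(default_factory=dict)   # (item, domain) -> MengResult
    convergent: dict = field(default_factory=dict)

    def summary_counts(self) -> dict:
        if self.classification is None:
            return {}
        counts = {c: 0 for c in CLASSES}
        for item in self.items:
            for d in self.domains:
                if d == self.own_domain[item]:
                    continue
                cls = self.classification.loc[item, d]
                if isinstance(cls, str) and cls in counts:
                    counts[cls] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for item in self.items:
            for d in self.domains:
                own = d == self.own_domain[item]
                rows.append({
                    "item": item, "domain": d, "own": own,
                    "r": self.r.loc[item, d], "n": self.n.loc[item, d],
                    "class": ("own" if own else
                              (self.classification.loc[item, d]
                               if self.classification is not None else "")),
                    "z": (self.z.loc[item, d]
                          if self.z is not None and not own else np.nan),
                    "p": (self.p.loc[item, d]
                          if self.p is not None and not own else np.nan),
                    "convergent": self.convergent.get(item) if own else None,
                })
        return pd.DataFrame(rows)


def domain_score(matrix: ResponseMatrix, items: list[str],
                 exclude_item: str | None = None,
                 config: AnalysisConfig | None = None) -> np.ndarray:
    """Summated domain score, optionally excluding one item.

    Applies the scoring module's imputation rule; respondents failing it
    get missing scores.
    """
    ids = [i for i in items if i != exclude_item]
    if not ids:
        raise ValueError("no items left after exclusion")
    scores, _ = score_scale(matrix, ids, config)
    return scores


def _pairwise_r(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return np.nan, n
    return float(np.corrcoef(x[ok], y[ok])[0, 1]), n


def item_domain_matrix(matrix: ResponseMatrix,
                       instrument: InstrumentDefinition,
                       corrected: bool = True,
                       config: AnalysisConfig | None = None) -> ScalingMatrix:
    """Item x domain Pearson correlation matrix.

    ``corrected=True`` applies the overlap correction: each item's
    own-domain score excludes the item.  A single-item domain under the
    correction yields a not-applicable own cell.  Standalone items are
    excluded from the matrix.
    """
    config = config or AnalysisConfig()
    domains = [d for d in instrument.domains if instrument.domain_items(d)]
    if len(domains) < 2:
        raise ValueError("need at least 2 non-empty domains")
    items = [i for i in instrument.item_ids
             if instrument.domain_of(i) is not None]
    own = {i: instrument.domain_of(i) for i in items}

    dscores = pd.DataFrame({
        d: domain_score(matrix, instrument.domain_items(d), config=config)
        for d in domains})
    own_scores = {}
    r = pd.DataFrame(index=items, columns=domains, dtype=float)
    n = pd.DataFrame(0, index=items, columns=domains, dtype=int)
    convergent = {}
    for item in items:
        x = matrix.item(item)
        for d in domains:
            if d == own[item] and corrected:
                dom_items = instrument.domain_items(d)
                if len(dom_items) < 2:
                    own_scores[item] = np.full(matrix.n, np.nan)
                    r.loc[item, d] = np.nan
                    n.loc[item, d] = 0
                    convergent[item] = None
                    continue
                score = domain_score(matrix, dom_items, exclude_item=item,
                                     config=config)
            else:
                score = dscores[d].to_numpy()
            if d == own[item]:
                own_scores[item] = score
            rr, nn = _pairwise_r(x, score)
            r.loc[item, d] = rr
            n.loc[item, d] = nn
        own_r = r.loc[item, own[item]]
        convergent[item] = (bool(own_r >= config.convergent_r)
                            if np.isfinite(own_r) else None)
    return ScalingMatrix(
        items=items, domains=domains, own_domain=own,
        r=r, n=n, corrected=corrected,
        domain_scores=dscores,
        own_scores=pd.DataFrame(own_scores),
        convergent=convergent,
    )


def classify_cells(scaling: ScalingMatrix,
                   config: AnalysisConfig | None = None) -> ScalingMatrix:
    """Run the Meng test for every off-diagonal cell and classify it.

    N per comparison is the smaller of the two cells' pairwise-complete
    counts; r_yy is the correlation between the two domain scores (the
    item-corrected own score when the matrix is corrected).
    """
    config = config or AnalysisConfig()
    cls = pd.DataFrame("", index=scaling.items, columns=scaling.domains)
    zf = pd.DataFrame(np.nan, index=scaling.items, columns=scaling.domains)
    pf = pd.DataFrame(np.nan, index=scaling.items, columns=scaling.domains)
    for item in scaling.items:
        own_d = scaling.own_domain[item]
        r1 = scaling.r.loc[item, own_d]
        own_score = scaling.own_scores[item].to_numpy()
        for d in scaling.domains:
            if d == own_d:
                continue
            r2 = scaling.r.loc[item, d]
            if not (np.isfinite(r1) and np.isfinite(r2)):
                cls.loc[item, d] = "not_applicable"
                continue
            r_yy, _ = _pairwise_r(own_score,
                                  scaling.domain_scores[d].to_numpy())
            n_used = int(min(scaling.n.loc[item, own_d],
                             scaling.n.loc[item, d]))
            if r1 == r2:
                res = MengResult(float(r1), float(r2), float(r_yy),
                                 n_used, 0.0, 1.0)
            else:
                res = meng_z_test(float(r1), float(r2), float(r_yy), n_used)
            scaling.meng[(item, d)] = res
            zf.loc[item, d] = res.z
            pf.loc[item, d] = res.p
            sig = res.p < config.alpha_level
            if r1 > r2:
                cls.loc[item, d] = "success" if sig else "probable"
            elif r1 < r2:
                cls.loc[item, d] = "failure" if sig else "possible"
            else:
                cls.loc[item, d] = "probable"
    scaling.classification = cls
    scaling.z = zf
    scaling.p = pf
    return scaling


@dataclass(frozen=True)
class RescalingProposal:
    item: str
    from_domain: str
    to_domain: str
    rationale: str


def propose_rescaling(scaling: ScalingMatrix) -> list[RescalingProposal]:
    """Propose moving items with scaling failures to their best domain.

    For every item with at least one failure cell the domain with the
    maximal correlation is proposed.  Proposals only: the final assignment
    is a user decision fed back as a new instrument definition.
    """
    if scaling.classification is None:
        raise ValueError("classify_cells must run before proposing rescaling")
    proposals = []
    for item in scaling.items:
        row_cls = scaling.classification.loc[item]
        if not (row_cls == "failure").any():
            continue
        rs = scaling.r.loc[item].astype(float)
        best = rs.idxmax()
        if best == scaling.own_domain[item]:
            continue
        proposals.append(RescalingProposal(
            item=item,
            from_domain=scaling.own_domain[item],
            to_domain=str(best),
            rationale=(f"r with {best} = {rs[best]:.2f} exceeds own-domain "
                       f"r = {rs[scaling.own_domain[item]]:.2f} "
                       f"with a significant difference"),
        ))
    return proposals
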