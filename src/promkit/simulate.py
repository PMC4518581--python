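"""Synthetic questionnaire cohorts with known latent structure.

The generator emulates a small patient-reported-outcome development cohort:
respondents carry four correlated latent traits (exertional dyspnea, cough,
fatigue, emotional well-being); each item is driven by one trait through
the Partial Credit Model (the same probability code the Rasch module
estimates with, so simulation and estimation cannot drift apart); defective
items are planted for the item-reduction stage (too few used categories,
heavy missingness, floor-heavy response distributions, redundant
near-duplicates); and a percent-predicted-FEV1-like severity covariate is
linked negatively to the dyspnea and fatigue traits but not to cough, with
a derived supplemental-oxygen indicator.

Missingness is completely at random.  Each item's latent propensity is a
mixture of its trait and item-specific variance (``item_loading``, default
0.85): real questionnaire items are imperfect indicators, and a loading
below 1 keeps distinct same-trait items from crossing the redundancy
threshold by sampling accident while planted duplicates still stand out.
Redundant partners share both the partner's realized latent propensity
(plus a Gaussian perturbation) and its categorization random draw, so the
observed pair correlation is high but below 1 while each item's marginal
distribution remains exactly PCM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnalysisConfig, InstrumentDefinition, ItemDef, ResponseMatrix
from .rasch import pcm_category_probs

TRAITS = ("exertional_dyspnea", "cough", "fatigue", "emotional")
COMPOSITE = "composite"  # equally weighted mix of all traits (standalone items)

#: defect classes the item-reduction stage is expected to catch
DEFECTS = ("none", "restricted_category", "high_missing", "floor_heavy",
           "redundant", "conceptual")


@dataclass(frozen=True)
class SimItem:
    """Generating recipe for one item."""

    id: str
    trait: str                      # a trait name or COMPOSITE
    steps: tuple[float, ...]        # PCM step difficulties, logits
    domain: str | None              # hypothesized domain (None = standalone)
    defect: str = "none"
    missing_prob: float | None = None     # overrides background rate
    redundant_partner: str | None = None
    redundant_sd: float = 0.1


@dataclass
class GeneratorSpec:
    """Cohort recipe: traits, items, defects, severity link, seed."""

    n_respondents: int = 69
    trait_names: tuple[str, ...] = TRAITS
    trait_correlation: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_CORR.copy())
    items: list[SimItem] = field(default_factory=list)
    #: correlation between an item's latent propensity and its trait; the
    #: remaining variance is item-specific.  1.0 makes items pure
    #: functions of the trait (useful for parameter-recovery studies).
    item_loading: float = 0.85
    missing_rate_background: float = 0.01
    severity_intercept: float = 65.0
    severity_slopes: dict = field(
        default_factory=lambda: {"exertional_dyspnea": -10.0, "fatigue": -8.0})
    severity_noise_sd: float = 14.0
    oxygen_cutoff: float = 60.0
    oxygen_misclass: float = 0.05
    spiro_window_days_range: tuple[int, int] = (0, 120)
    seed: int = 0

    def __post_init__(self):
        R = np.asarray(self.trait_correlation, dtype=float)
        k = len(self.trait_names)
        if R.shape != (k, k) or not np.allclose(R, R.T) \
                or not np.allclose(np.diag(R), 1.0):
            raise ValueError("trait_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("trait_correlation must be positive definite")
        self.trait_correlation = R
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in spec")
        for it in self.items:
            if it.trait not in (*self.trait_names, COMPOSITE):
                raise ValueError(f"item {it.id}: unknown trait {it.trait!r}")
            if it.defect not in DEFECTS:
                raise ValueError(f"item {it.id}: unknown defect {it.defect!r}")
            if it.defect == "redundant":
                if it.redundant_partner not in ids:
                    raise ValueError(
                        f"redundant item {it.id}: partner not in spec")
                partner = next(p for p in self.items if p.id == it.redundant_partner)
                if partner.defect == "redundant":
                    raise ValueError("redundant partner must itself be clean")

    def instrument(self, covariates=None) -> InstrumentDefinition:
        """Hypothesized instrument definition matching this spec."""
        domains = [d for d in self.trait_names
                   if any(it.domain == d for it in self.items)]
        items = [
            ItemDef(it.id,
                    left_anchor="Not at all affected over the last 48 hours",
                    right_anchor="Severely affected over the last 48 hours",
                    domain=it.domain)
            for it in self.items
        ]
        kwargs = {} if covariates is None else {"covariates": covariates}
        return InstrumentDefinition(items=items, domains=list(domains), **kwargs)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    trait_scores: pd.DataFrame          # n x (traits + composite)
    item_trait: dict                    # item id -> generating trait
    true_steps: dict                    # item id -> np.ndarray of steps
    defect_labels: dict                 # item id -> defect class
    severity: np.ndarray                # before clipping to [0, 150]
    oxygen_true: np.ndarray             # bool, before misclassification
    respondent_ids: list


def _draw_pcm(theta: np.ndarray, steps: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF categorization shared between partners of redundant pairs."""
    p = pcm_category_probs(theta, np.asarray(steps, dtype=float))
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def generate_cohort(spec: GeneratorSpec) -> tuple[ResponseMatrix, GroundTruth]:
    """Draw one cohort; deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_respondents
    k = len(spec.trait_names)
    R = spec.trait_correlation
    eta = rng.standard_normal((n, k)) @ np.linalg.cholesky(R).T
    comp_sd = np.sqrt(R.sum() / k**2)
    composite = eta.mean(axis=1) / comp_sd
    traits = pd.DataFrame(eta, columns=list(spec.trait_names))
    traits[COMPOSITE] = composite

    theta_of = {t: eta[:, i] for i, t in enumerate(spec.trait_names)}
    theta_of[COMPOSITE] = composite

    responses = {}
    u_store: dict[str, np.ndarray] = {}
    latent_store: dict[str, np.ndarray] = {}
    lam = spec.item_loading
    uniq = np.sqrt(max(0.0, 1.0 - lam**2))
    for it in spec.items:
        if it.defect == "redundant":
            latent = (latent_store[it.redundant_partner]
                      + rng.normal(scale=it.redundant_sd, size=n))
            u = u_store[it.redundant_partner]
        else:
            latent = lam * theta_of[it.trait]
            if uniq > 0:
                latent = latent + uniq * rng.standard_normal(n)
            u = rng.random(n)
        latent_store[it.id] = latent
        u_store[it.id] = u
        cats = _draw_pcm(latent, it.steps, u)
        responses[it.id] = cats + 1.0  # back to the 1..6 scale

    df = pd.DataFrame(responses)
    for it in spec.items:
        p_miss = (it.missing_prob if it.missing_prob is not None
                  else spec.missing_rate_background)
        if p_miss > 0:
            mask = rng.random(n) < p_miss
            df.loc[mask, it.id] = np.nan

    slopes = np.array([spec.severity_slopes.get(t, 0.0) for t in spec.trait_names])
    severity = (spec.severity_intercept + eta @ slopes
                + rng.normal(scale=spec.severity_noise_sd, size=n))
    oxygen_true = severity < spec.oxygen_cutoff
    flip = rng.random(n) < spec.oxygen_misclass
    oxygen = np.where(flip ^ oxygen_true, "ever", "never")
    lo, hi = spec.spiro_window_days_range
    window = rng.integers(lo, hi + 1, size=n)

    cov = pd.DataFrame({
        "severity_pct": np.clip(severity, 0.0, 150.0),
        "spiro_window_days": window,
        "oxygen_use": oxygen,
    })
    matrix = ResponseMatrix(df, cov, respondent_ids=list(range(n)))
    truth = GroundTruth(
        trait_scores=traits,
        item_trait={it.id: it.trait for it in spec.items},
        true_steps={it.id: np.asarray(it.steps, dtype=float) for it in spec.items},
        defect_labels={it.id: it.defect for it in spec.items},
        severity=severity,
        oxygen_true=oxygen_true,
        respondent_ids=list(range(n)),
    )
    return matrix, truth


DEFAULT_TRAIT_CORR = np.array([
    # dysp   cough  fat    emot
    [1.00, 0.10, 0.50, 0.40],
    [0.10, 1.00, 0.10, 0.10],
    [0.50, 0.10, 1.00, 0.45],
    [0.40, 0.10, 0.45, 1.00],
])

_SPEC_BUILD_SEED = 20_240_815  # instrument recipe is fixed across cohort seeds


def _clean_steps(rng) -> tuple[float, ...]:
    b = rng.uniform(-1.0, 1.0)
    s = np.sort(b + np.linspace(-1.3, 1.3, 5) + rng.uniform(-0.15, 0.15, 5))
    return tuple(np.clip(s, -2.0, 2.0))


def _floor_steps(rng) -> tuple[float, ...]:
    # +3 logit shift puts ~3/4 of a theta~N(0,1) population at the floor,
    # far enough above the 49% deletion threshold to be unambiguous at n=69
    b = rng.uniform(-0.3, 0.3)
    return tuple(np.sort(b + 3.0 + np.linspace(-1.3, 1.3, 5)
                         + rng.uniform(-0.15, 0.15, 5)))


def _restricted_steps(rng) -> tuple[float, ...]:
    # extreme categories unreachable in practice: P(category) < 1e-4 at |theta|<=3
    j = rng.uniform(-0.1, 0.1)
    return (-13.0, -2.0 + j, 0.0 + j, 2.0 + j, 13.0)


def default_cohort_spec(n_respondents: int = 69, seed: int = 0) -> GeneratorSpec:
    """The default 69 x 56 development-cohort recipe.

    29 clean items in four domains (13 dyspnea / 6 cough / 5 fatigue /
    5 emotional, echoing the final published structure), 3 clean standalone
    items driven by a composite of all traits, and 24 planted defects:
    3 restricted-category, 2 heavy-missing (35%), 10 floor-heavy,
    7 redundant near-duplicates, and 2 standalone "relationship" items
    earmarked for conceptual deletion.
    """
    rng = np.random.default_rng(_SPEC_BUILD_SEED)
    dysp, cough, fat, emot = TRAITS
    items: list[SimItem] = []

    def add(id_, trait, domain, defect="none", **kw):
        steps = kw.pop("steps", None)
        if steps is None:
            steps = {
                "floor_heavy": _floor_steps,
                "restricted_category": _restricted_steps,
            }.get(defect, _clean_steps)(rng)
        items.append(SimItem(id_, trait, tuple(steps), domain, defect, **kw))

    for i in range(13):
        add(f"dysp{i+1:02d}", dysp, dysp)
    for i in range(6):
        add(f"cough{i+1:02d}", cough, cough)
    for i in range(5):
        add(f"fat{i+1:02d}", fat, fat)
    for i in range(5):
        add(f"emot{i+1:02d}", emot, emot)
    for i in range(3):
        add(f"glob{i+1:02d}", COMPOSITE, None)

    add("dysp14", dysp, dysp, "restricted_category")
    add("dysp15", dysp, dysp, "restricted_category")
    add("cough07", cough, cough, "restricted_category")
    add("fat06", fat, fat, "high_missing", missing_prob=0.35)
    add("emot06", emot, emot, "high_missing", missing_prob=0.35)
    for i, (tr, dm) in enumerate([(dysp, dysp)] * 4 + [(cough, cough)] * 2
                                 + [(fat, fat)] * 2 + [(emot, emot)] * 2):
        add(f"floor{i+1:02d}", tr, dm, "floor_heavy")
    partners = ["dysp01", "dysp02", "dysp03", "cough01", "cough02",
                "fat01", "emot01"]
    for i, p in enumerate(partners):
        tr = next(it.trait for it in items if it.id == p)
        dm = next(it.domain for it in items if it.id == p)
        # same steps as the partner: a near-duplicate wording of the same
        # question; duplicates are skipped more often (10% missing), which
        # also makes the redundancy tie-break keep the better-measured member
        st = next(it.steps for it in items if it.id == p)
        add(f"dup{i+1:02d}", tr, dm, "redundant", steps=st,
            redundant_partner=p, redundant_sd=0.1, missing_prob=0.10)
    add("rel01", emot, None, "conceptual")
    add("rel02", emot, None, "conceptual")

    return GeneratorSpec(n_respondents=n_respondents, items=items, seed=seed)


def default_analysis_config(seed: int = 0) -> AnalysisConfig:
    """Thresholds matched to the default cohort's planted defects."""
    return AnalysisConfig(conceptual_deletions=["rel01", "rel02"], seed=seed)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Delimited sidecar: per-item truth plus per-respondent latent values."""
    items = pd.DataFrame({
        "item": list(truth.item_trait),
        "trait": [truth.item_trait[i] for i in truth.item_trait],
        "defect": [truth.defect_labels[i] for i in truth.item_trait],
        "steps": [";".join(f"{s:.4f}" for s in truth.true_steps[i])
                  for i in truth.item_trait],
    })
    persons = truth.trait_scores.copy()
    persons.insert(0, "respondent_id", truth.respondent_ids)
    persons["severity"] = truth.severity
    persons["oxygen_true"] = truth.oxygen_true
    with open(path, "w") as fh:
        fh.write("# items\n")
        items.to_csv(fh, index=False)
        fh.write("# persons\n")
        persons.to_csv(fh, index=False)
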