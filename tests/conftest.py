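import numpy as np
import pandas as pd
import pytest

import promkit as pk

# ---------------------------------------------------------------------------
# hand-worked deletion fixture: one item trips each of the first three rules,
# one redundant pair, one conceptual deletion, two clean survivors.
# Expected outcome (derived by applying the rules by hand):
#   itemA  deleted  stage 1 (4 categories used)
#   itemB  deleted  stage 2 (3/10 missing)
#   itemC  flagged_retained stage 3 (6/10 floor, in retain_overrides)
#   itemD  deleted  stage 4 (r = 0.94 with itemE; equal missing, higher floor)
#   itemF  deleted  stage 5 (conceptual)
#   itemE, itemG, itemH retained
GOLDEN_RESPONSES = {
    "itemA": [1, 2, 3, 4, 1, 2, 3, 4, 1, 2],
    "itemB": [1, 2, 3, 4, 5, 6, 6, None, None, None],
    "itemC": [1, 1, 1, 1, 1, 1, 2, 3, 4, 5],
    "itemD": [1, 2, 3, 4, 5, 6, 1, 2, 3, 4],
    "itemE": [2, 1, 3, 4, 5, 6, 2, 2, 3, 4],
    "itemF": [2, 3, 4, 5, 6, 1, 2, 3, 4, 5],
    "itemG": [6, 5, 4, 3, 2, 1, 6, 5, 4, 3],
    "itemH": [3, 1, 4, 6, 2, 5, 3, 1, 4, 6],
}


@pytest.fixture
def golden_matrix():
    return pk.ResponseMatrix(pd.DataFrame(GOLDEN_RESPONSES, dtype=float))


@pytest.fixture
def golden_instrument():
    return pk.InstrumentDefinition(
        items=[pk.ItemDef(i, "left", "right", "d1") for i in GOLDEN_RESPONSES],
        domains=["d1"],
    )


@pytest.fixture
def golden_config():
    return pk.AnalysisConfig(retain_overrides=["itemC"],
                             conceptual_deletions=["itemF"])


# ---------------------------------------------------------------------------
# shared synthetic cohorts (session-scoped: several modules reuse them)

@pytest.fixture(scope="session")
def default_spec():
    return pk.default_cohort_spec(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    matrix, truth = pk.generate_cohort(default_spec)
    return matrix, truth, default_spec.instrument()


@pytest.fixture(scope="session")
def big_cohort():
    """n=500 variant of the default cohort, for stable correlations."""
    spec = pk.default_cohort_spec(n_respondents=500, seed=2)
    matrix, truth = pk.generate_cohort(spec)
    return matrix, truth, spec.instrument()


@pytest.fixture(scope="session")
def big_survivors(big_cohort):
    """Deletion-stage survivors of the n=500 cohort."""
    matrix, truth, inst = big_cohort
    cfg = pk.default_analysis_config(seed=2)
    report = pk.run_deletion_algorithm(matrix, inst, cfg)
    return inst.subset(report.retained_ids())


def make_matrix(arrays: dict) -> pk.ResponseMatrix:
    """Build a ResponseMatrix from plain lists (None = missing)."""
    return pk.ResponseMatrix(pd.DataFrame(arrays, dtype=float))


@pytest.fixture(scope="session")
def recovery_items():
    """29 three-category items for parameter-recovery studies.

    Three response categories concentrate responses on each threshold, so
    each step difficulty is estimated precisely at n=500.
    """
    rng = np.random.default_rng(42)
    items = []
    for i in range(29):
        b = rng.uniform(-1.2, 1.2)
        steps = tuple(np.sort(b + np.linspace(-0.9, 0.9, 2)
                              + rng.uniform(-0.1, 0.1, 2)))
        items.append(pk.SimItem(f"it{i:02d}", "hrql", steps, "hrql"))
    return items
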