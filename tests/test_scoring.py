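import numpy as np
import pandas as pd
import pytest
from scipy import stats

import promkit as pk

from conftest import make_matrix

NA = None


class TestScoreScale:
    def test_half_answered_imputes_with_unrounded_mean(self):
        m = make_matrix({"a": [2], "b": [4], "c": [NA], "d": [NA]})
        s, imputed = pk.score_scale(m, ["a", "b", "c", "d"])
        assert s[0] == pytest.approx(12.0)   # 2 + 4 + 3 + 3
        assert imputed[0]

    def test_below_half_answered_is_missing(self):
        m = make_matrix({"a": [2], "b": [NA], "c": [NA], "d": [NA]})
        s, _ = pk.score_scale(m, ["a", "b", "c", "d"])
        assert np.isnan(s[0])

    def test_scale_extremes(self):
        cols = {f"i{k}": [1, 6] for k in range(13)}
        m = make_matrix(cols)
        s, imputed = pk.score_scale(m, list(cols))
        assert s[0] == pytest.approx(13.0)
        assert s[1] == pytest.approx(78.0)
        assert not imputed.any()
        assert pk.scale_range(list(cols)) == (13, 78)

    def test_complete_data_equals_plain_sum(self):
        rng = np.random.default_rng(4)
        cols = {f"i{k}": rng.integers(1, 7, 50) for k in range(6)}
        m = make_matrix(cols)
        s, imputed = pk.score_scale(m, list(cols))
        assert np.allclose(s, sum(cols.values()))
        assert not imputed.any()

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        cols = {f"i{k}": rng.integers(1, 7, 30).astype(float) for k in range(4)}
        cols["i0"][:6] = np.nan
        m = make_matrix(cols)
        s1, _ = pk.score_scale(m, ["i0", "i1", "i2", "i3"])
        s2, _ = pk.score_scale(m, ["i3", "i1", "i0", "i2"])
        assert np.allclose(s1, s2, equal_nan=True)


class TestCronbachAlpha:
    def test_exact_compound_symmetry_closed_form(self):
        """Data whitened to an exactly compound-symmetric sample covariance:
        alpha equals k*rbar / (1 + (k-1)*rbar) to 1e-10."""
        k, n, rbar = 5, 60, 0.5
        rng = np.random.default_rng(11)
        X = rng.standard_normal((n, k))
        Xc = X - X.mean(axis=0)
        S = np.cov(Xc, rowvar=False)
        target = np.full((k, k), rbar) + (1 - rbar) * np.eye(k)
        Y = Xc @ np.linalg.inv(np.linalg.cholesky(S).T) \
            @ np.linalg.cholesky(target).T
        # shift/scale into the 1..6 response range is unnecessary: alpha is
        # scale-free, so feed the whitened data through a raw ResponseMatrix
        m = pk.ResponseMatrix.__new__(pk.ResponseMatrix)
        m.responses = pd.DataFrame(Y, columns=[f"i{j}" for j in range(k)])
        m.covariates = pd.DataFrame(index=m.responses.index)
        m.respondent_ids = list(range(n))
        alpha, mean_r = pk.cronbach_alpha(m, list(m.responses.columns))
        expected = k * rbar / (1 + (k - 1) * rbar)
        assert alpha == pytest.approx(expected, abs=1e-10)
        assert mean_r == pytest.approx(rbar, abs=1e-10)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(12)
        cols = {f"i{k}": rng.integers(1, 7, 2000) for k in range(4)}
        m = make_matrix(cols)
        alpha, _ = pk.cronbach_alpha(m, list(cols))
        assert alpha == pytest.approx(0.0, abs=0.05)

    def test_duplicated_item_drives_alpha_to_one(self):
        rng = np.random.default_rng(13)
        x = rng.integers(1, 7, 100)
        alphas = []
        for k in (2, 4, 8):
            cols = {f"i{j}": x for j in range(k)}
            m = make_matrix(cols)
            a, _ = pk.cronbach_alpha(m, list(cols))
            alphas.append(a)
        assert alphas[0] == pytest.approx(1.0)
        assert all(a == pytest.approx(1.0) for a in alphas)

    def test_errors(self):
        m = make_matrix({"a": [1, 2, 3], "b": [3, 2, 1]})
        with pytest.raises(ValueError):
            pk.cronbach_alpha(m, ["a"])
        m2 = make_matrix({"a": [1, 2, NA], "b": [3, 2, 1]})
        with pytest.raises(ValueError, match="complete"):
            pk.cronbach_alpha(m2, ["a", "b"])

    def test_response_shift_leaves_alpha_unchanged(self):
        rng = np.random.default_rng(14)
        base = {f"i{k}": rng.integers(1, 6, 200) for k in range(4)}
        m1 = make_matrix(base)
        m2 = make_matrix({k: v + 1 for k, v in base.items()})
        a1, r1 = pk.cronbach_alpha(m1, list(base))
        a2, r2 = pk.cronbach_alpha(m2, list(base))
        assert a1 == pytest.approx(a2)
        assert r1 == pytest.approx(r2)


class TestFloorCeilingScale:
    def test_percentages(self):
        fl, ce = pk.floor_ceiling_scale(np.array([13, 20, 78, 78.0]), (13, 78))
        assert (fl, ce) == (25.0, 50.0)

    def test_no_extremes(self):
        fl, ce = pk.floor_ceiling_scale(np.array([20, 30.0]), (13, 78))
        assert (fl, ce) == (0.0, 0.0)

    def test_fractional_imputed_score_is_not_floor(self):
        fl, ce = pk.floor_ceiling_scale(np.array([13.5]), (13, 78))
        assert (fl, ce) == (0.0, 0.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            pk.floor_ceiling_scale(np.array([np.nan]), (1, 6))


class TestExternalCorrelations:
    def test_window_filter_decrements_n(self):
        rng = np.random.default_rng(15)
        resp = pd.DataFrame({"a": rng.integers(1, 7, 10).astype(float)})
        cov = pd.DataFrame({
            "severity_pct": rng.uniform(30, 100, 10),
            "spiro_window_days": [10] * 9 + [100],
        })
        m = pk.ResponseMatrix(resp, cov)
        inst = pk.InstrumentDefinition(
            items=[pk.ItemDef("a", "L", "R", "d")], domains=["d"])
        ss = pk.score_set(m, inst)
        tab = pk.external_correlations(ss, m)
        assert (tab.n == 9).all()

    def test_constant_scores_not_estimable(self):
        resp = pd.DataFrame({"a": [3.0] * 8})
        cov = pd.DataFrame({"severity_pct": np.linspace(30, 90, 8),
                            "spiro_window_days": [0] * 8})
        m = pk.ResponseMatrix(resp, cov)
        inst = pk.InstrumentDefinition(
            items=[pk.ItemDef("a", "L", "R", "d")], domains=["d"])
        tab = pk.external_correlations(pk.score_set(m, inst), m)
        assert not tab.estimable.any()

    def test_sign_pattern_on_default_cohort(self, big_cohort, big_survivors):
        """Dyspnea/fatigue/total correlate negatively with severity; cough
        does not (direction only, magnitudes are not targets)."""
        matrix, _, _ = big_cohort
        tab = pk.external_correlations(
            pk.score_set(matrix, big_survivors), matrix)
        r = dict(zip(tab.scale, tab.r))
        assert r["exertional_dyspnea"] < -0.4
        assert r["fatigue"] < -0.3
        assert r["total"] < -0.4
        assert abs(r["cough"]) < 0.15


class TestTertiles:
    def test_quantile_convention(self):
        g, cuts = pk.tertile_groups(np.arange(1.0, 10.0))
        assert list(g) == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_planted_monotone_effect_direction(self, big_cohort,
                                               big_survivors):
        matrix, _, _ = big_cohort
        score, _ = pk.score_scale(
            matrix, big_survivors.domain_items("exertional_dyspnea"))
        rep = pk.tertile_contrast(score, matrix.covariate("severity_pct"))
        assert rep.group_mean[0] > rep.group_mean[2]
        assert rep.contrast_p < 0.05

    def test_too_few_respondents_rejected(self):
        with pytest.raises(ValueError):
            pk.tertile_contrast(np.arange(4.0), np.arange(4.0))

    def test_massive_ties_leave_empty_tertile(self):
        sev = np.array([1.0] * 9 + [2.0, 3.0])
        with pytest.raises(ValueError, match="tertile"):
            pk.tertile_contrast(np.arange(11.0), sev)


class TestGroupComparison:
    def test_identical_groups(self):
        s = np.array([1, 2, 3, 1, 2, 3.0])
        g = np.array([True, True, True, False, False, False])
        rep = pk.group_comparison(s, g)
        assert rep.difference == pytest.approx(0.0)
        assert rep.p == pytest.approx(1.0)
        assert rep.sdu == pytest.approx(0.0)

    def test_published_oxygen_table_differences_recompute(self):
        """Group-mean differences recomputed from the published group means
        match the printed difference column for the scales whose printed
        values reconcile exactly."""
        stats_tab = pk.OXYGEN_GROUP_STATS
        printed = {"exertional_dyspnea": 15.4, "cough": 3.1,
                   "fatigue": 6.5, "emotional": 4.8}
        for scale, expect in printed.items():
            ever = stats_tab[scale]["ever"]
            never = stats_tab[scale]["never"]
            rep = pk.group_comparison_from_summary(*ever, *never)
            assert rep.difference == pytest.approx(expect, abs=1e-9)

    def test_small_group_reports_means_without_p(self):
        s = np.array([1, 2, 3, 4.0])
        g = np.array([True, False, False, False])
        rep = pk.group_comparison(s, g)
        assert rep.mean[0] == pytest.approx(1.0)
        assert np.isnan(rep.p)

    def test_null_rejection_rate_calibrated(self):
        """Pooled t-test type-I error ~5% when both groups share one
        distribution (vectorized null simulation)."""
        rng = np.random.default_rng(16)
        reps, n1, n2 = 2000, 30, 35
        x = rng.standard_normal((reps, n1))
        y = rng.standard_normal((reps, n2))
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
        # sanity: scipy's vectorized test agrees with our per-rep report
        rep0 = pk.group_comparison(
            np.concatenate([x[0], y[0]]),
            np.array([True] * n1 + [False] * n2))
        assert rep0.p == pytest.approx(p[0], rel=1e-10)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_welch_flag_changes_test_not_descriptives(self):
        rng = np.random.default_rng(17)
        s = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 3, 40)])
        g = np.array([True] * 20 + [False] * 40)
        pooled = pk.group_comparison(s, g)
        welch = pk.group_comparison(s, g, welch=True)
        assert welch.mean == pooled.mean
        assert welch.difference == pooled.difference
        assert welch.p != pooled.p


class TestScoreSetAndReports:
    def test_total_is_sum_over_items_not_domains(self, big_cohort,
                                                 big_survivors):
        matrix, _, _ = big_cohort
        ss = pk.score_set(matrix, big_survivors)
        assert ss.ranges["total"] == (32, 192)
        # standalone items contribute to the total but no domain
        k_domains = sum(len(ss.scales[d]) for d in big_survivors.domains)
        assert len(ss.scales["total"]) == k_domains + 3

    def test_reliability_report_structure(self, big_cohort, big_survivors):
        matrix, _, _ = big_cohort
        rel = pk.reliability_report(matrix, big_survivors)
        assert set(rel.scale) == {"exertional_dyspnea", "cough", "fatigue",
                                  "emotional", "total"}
        alphas = dict(zip(rel.scale, rel.alpha))
        # clean domains are internally consistent at n=500
        assert all(a > 0.65 for a in alphas.values())
        assert alphas["exertional_dyspnea"] > 0.85
        assert alphas["total"] > 0.85
        rng = dict(zip(rel.scale, rel.range_possible))
        assert rng["exertional_dyspnea"] == "13-78"
        assert rng["total"] == "32-192"

    def test_oxygen_groups_higher_on_all_but_cough(self, big_cohort,
                                                   big_survivors):
        matrix, _, _ = big_cohort
        val = pk.validity_report(matrix, big_survivors)
        for scale, rep in val["oxygen"].items():
            if scale == "cough":
                assert abs(rep.sdu) < 0.25
            else:
                assert rep.sdu > 0.3
                assert rep.p < 0.05
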