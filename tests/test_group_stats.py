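"""Paired Wilcoxon statistics, ratio curves and cohort summaries."""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sst

from pulsehrv.group_stats import (
    geometric_mean_se,
    median_se,
    pointwise_thresholds,
    ratio_curve,
    summarize_indexes,
    wilcoxon_paired,
)


def enumerate_wilcoxon(d):
    """Exact V and two-sided p by exhaustive enumeration of sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sst.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    vs = np.array([sum(r for r, s in zip(ranks, signs) if s)
                   for signs in product([0, 1], repeat=len(d))])
    p = min(1.0, 2 * min((vs <= v_obs).mean(), (vs >= v_obs).mean()))
    return v_obs, p


class TestWilcoxon:
    def test_all_positive_differences_give_maximal_statistic(self):
        v, p = wilcoxon_paired(np.arange(1.0, 22.0), np.zeros(21))
        assert v == 21 * 22 / 2 == 231
        assert p < 0.01

    def test_identical_samples_are_undefined(self):
        v, p = wilcoxon_paired(np.ones(10), np.ones(10))
        assert np.isnan(v) and np.isnan(p)

    def test_alternating_signs_match_enumeration(self):
        d = np.array([1, -2, 3, -4, 5, -6, 7, -8, 9, -10], dtype=float)
        v, p = wilcoxon_paired(d, np.zeros(10))
        v_ref, p_ref = enumerate_wilcoxon(d)
        assert v == v_ref and p == pytest.approx(p_ref, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_tied_data_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.standard_normal(11), 1)
        if (d == 0).all():
            return
        v, p = wilcoxon_paired(d, np.zeros(len(d)))
        v_ref, p_ref = enumerate_wilcoxon(d)
        assert v == v_ref and p == pytest.approx(p_ref, abs=1e-12)

    def test_agrees_with_scipy_exact_when_untied(self):
        rng = np.random.default_rng(42)
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        v, p = wilcoxon_paired(x, y)
        ref = sst.wilcoxon(x, y, alternative="two-sided", method="exact")
        assert min(v, 15 * 16 / 2 - v) == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_sign_flip_identity(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(18), rng.standard_normal(18)
        v1, _ = wilcoxon_paired(x, y)
        v2, _ = wilcoxon_paired(y, x)
        assert v1 + v2 == 18 * 19 / 2

    def test_normal_approximation_close_to_exact_at_25(self):
        import pulsehrv.group_stats as gs
        rng = np.random.default_rng(2)
        for _ in range(5):
            x, y = rng.standard_normal(25), rng.standard_normal(25)
            _, p_exact = wilcoxon_paired(x, y)
            old = gs.EXACT_MAX_N
            try:
                gs.EXACT_MAX_N = 1
                _, p_approx = wilcoxon_paired(x, y)
            finally:
                gs.EXACT_MAX_N = old
            assert abs(p_exact - p_approx) <= 0.01


class TestThresholds:
    def test_one_percent_threshold_at_least_five_percent_one(self):
        for n in (8, 10, 15, 21):  # 1% attainable only for n >= 8
            thr = pointwise_thresholds(n)
            assert thr[0.01] >= thr[0.05]
        thr6 = pointwise_thresholds(6)
        assert np.isfinite(thr6[0.05]) and np.isnan(thr6[0.01])

    def test_n5_five_percent_unattainable(self):
        thr = pointwise_thresholds(5)
        assert np.isnan(thr[0.05]) and np.isnan(thr[0.01])

    def test_n21_matches_exhaustive_tail_enumeration(self):
        # classical two-sided critical values for n = 21: V >= 173 (5%),
        # V >= 189 (1%), derived here from the full exact distribution
        dist = np.zeros(21 * 22 // 2 + 1)
        dist[0] = 1.0
        for r in range(1, 22):
            nxt = dist.copy()
            nxt[r:] += dist[:-r]
            dist = nxt
        dist /= dist.sum()
        sf = np.cumsum(dist[::-1])[::-1]
        expected = {}
        for level in (0.05, 0.01):
            ok = np.flatnonzero((2 * sf <= level) & (dist > 0))
            expected[level] = ok[0]
        thr = pointwise_thresholds(21)
        assert thr[0.05] == expected[0.05] == 173
        assert thr[0.01] == expected[0.01] == 189

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            pointwise_thresholds(10, levels=(1.5,))


class TestRatioCurve:
    def test_identical_curves_give_unit_ratio(self):
        curves = np.random.default_rng(0).random((8, 40)) + 1.0
        rc = ratio_curve(curves, curves, grid=np.arange(40))
        np.testing.assert_allclose(rc.median, 1.0)
        np.testing.assert_allclose(rc.q1, 1.0)

    def test_doubled_curves_give_ratio_two(self):
        rri = np.random.default_rng(1).random((8, 40)) + 1.0
        rc = ratio_curve(2.0 * rri, rri, grid=np.arange(40))
        np.testing.assert_allclose(rc.median, 2.0)
        assert (rc.V == 8 * 9 / 2).all()

    def test_zero_denominator_flagged_missing(self):
        rri = np.ones((6, 5))
        rri[:, 2] = 0.0
        rc = ratio_curve(np.ones((6, 5)), rri, grid=np.arange(5))
        assert np.isnan(rc.median[2]) and np.isfinite(rc.median[1])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            ratio_curve(np.ones((3, 5)), np.ones((3, 5)), grid=np.arange(5))


class TestSummaries:
    def test_identical_values_have_zero_median_se(self):
        med, se = median_se(np.full(12, 3.3), seed=0)
        assert med == 3.3 and se == pytest.approx(0.0, abs=1e-12)

    def test_geometric_mean_is_exp_mean_log(self):
        vals = np.exp(np.random.default_rng(2).standard_normal(20))
        gm, _ = geometric_mean_se(vals)
        assert gm == pytest.approx(np.exp(np.log(vals).mean()), rel=1e-12)

    def test_bootstrap_se_close_to_asymptotic_for_normal_median(self):
        rng = np.random.default_rng(3)
        ses = [median_se(rng.standard_normal(21), seed=s)[1] for s in range(40)]
        asymptotic = 1.2533 / np.sqrt(21)
        assert np.mean(ses) == pytest.approx(asymptotic, rel=0.30)

    def test_summary_table_layout_and_significance(self):
        rng = np.random.default_rng(4)
        rri = rng.random(12) + 1.0
        cohort = {"hf": {"RRI": rri, "SSI": rri * 1.5},
                  "alpha1": {"RRI": rri, "SSI": rri}}
        df = summarize_indexes(cohort, geometric=("hf",), seed=0)
        row = df[(df["index"] == "hf") & (df["kind"] == "SSI")].iloc[0]
        assert row["stars"] == "**"  # every subject increased
        assert "geo_mean" in df.columns
        ref_row = df[(df["index"] == "hf") & (df["kind"] == "RRI")].iloc[0]
        assert np.isnan(ref_row["p_vs_ref"])
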