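"""Statistical primitives against hand computations and independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from methscreen.stats import (
    bh_adjust,
    fisher_exact_2x2,
    km_estimate,
    logrank,
    pearson,
    spearman,
    two_sample_t,
)


class TestSpearman:
    def test_perfect_anti_monotone(self):
        r = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert r.statistic == pytest.approx(-1.0)
        assert r.p_value == 0.0

    def test_hand_computed_rho(self):
        # ranks equal values; Pearson of (1,2,3,4) vs (2,1,4,3) = 3/5
        r = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.statistic == pytest.approx(0.6)

    def test_ties_use_average_ranks(self):
        # y = (1,1,2,3) -> ranks (1.5,1.5,3,4); compare to explicit Pearson on ranks
        x = [10.0, 20.0, 30.0, 40.0]
        y = [1.0, 1.0, 2.0, 3.0]
        expected = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert spearman(x, y).statistic == pytest.approx(expected)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="4 complete pairs"):
            spearman([1, 2, 3], [3, 2, 1])

    def test_zero_rank_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_missing_dropped_pairwise(self):
        r = spearman([1, 2, 3, 4, np.nan], [8, 6, 4, 2, 1])
        assert r.n == 4
        assert r.statistic == pytest.approx(-1.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000), st.integers(5, 40))
    def test_matches_scipy_spearmanr(self, seed, n):
        """rho and the t-approximation p agree with scipy's implementation."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.3 * x
        ours = spearman(x, y)
        rho, p = sps.spearmanr(x, y)
        assert ours.statistic == pytest.approx(rho, abs=1e-12)
        assert ours.p_value == pytest.approx(p, abs=1e-9)

    def test_exact_permutation_close_to_t_for_moderate_rho(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        exact = spearman(x, y, method="exact")
        approx = spearman(x, y)
        assert abs(exact.p_value - approx.p_value) < 0.15
        assert exact.statistic == approx.statistic


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 50),
           st.sampled_from([0.05, 0.1, 0.2]))
    def test_rejections_match_classical_step_up(self, seed, m, alpha):
        """q < alpha reproduces the classical BH step-up rejection set."""
        rng = np.random.default_rng(seed)
        p = rng.random(m) ** 2
        q = bh_adjust(p)
        # independent oracle: largest k with p_(k) <= k*alpha/m, reject those
        order = np.argsort(p)
        ks = np.flatnonzero(p[order] <= (np.arange(1, m + 1) * alpha / m))
        expected = set(order[: ks[-1] + 1]) if len(ks) else set()
        # BH adjusted-p rule uses q <= alpha for exact boundary cases
        assert set(np.flatnonzero(q <= alpha)) == expected

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 60))
    def test_matches_statsmodels(self, seed, m):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(m)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm, atol=1e-12)


class TestTwoSampleT:
    def test_identical_groups(self):
        r = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_pooled_variance(self):
        r = two_sample_t([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.674, abs=1e-3)
        assert r.p_value == pytest.approx(0.0214, abs=2e-4)

    def test_swap_negates_t_keeps_p(self):
        a, b = [1.0, 2.2, 3.3, 1.8], [2.0, 4.0, 3.1]
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([2.0, 2.0], [2.0, 2.0])

    def test_group_too_small(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_sample_t([1.0], [2.0, 3.0])


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        from math import comb

        r = fisher_exact_2x2([[10, 0], [0, 10]])
        assert r.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert r.estimate == np.inf

    def test_published_island_table_bound(self):
        # 303/382 island-associated silenced genes vs 66.2% random baseline
        assert fisher_exact_2x2([[303, 79], [253, 129]]).p_value <= 1e-4

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])

    def test_odds_ratio_is_ad_over_bc(self):
        r = fisher_exact_2x2([[6, 2], [3, 9]])
        assert r.estimate == pytest.approx(6 * 9 / (2 * 3))

    @staticmethod
    def _enumeration_p(table):
        """Oracle: sum hypergeometric probabilities <= that of the observed table."""
        (a, b), (c, d) = table
        r1, r2, c1 = a + b, c + d, a + c
        n = r1 + r2
        probs = {
            x: sps.hypergeom.pmf(x, n, r1, c1)
            for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        }
        p_obs = probs[a]
        return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_full_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 16, size=(2, 2))
        if t.sum() == 0:
            t[0, 0] = 1
        assert t.sum() <= 60
        ours = fisher_exact_2x2(t)
        assert ours.p_value == pytest.approx(self._enumeration_p(t), rel=1e-6)


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3], [3, 5, 7]).statistic == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson([1, 2, 3], [-1, -2, -3]).statistic == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson([1, 2, 3], [1, 3, 2]).statistic == pytest.approx(0.5)

    def test_too_few(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [2, 1])


class TestKaplanMeier:
    def test_two_events_no_censoring(self):
        t, s = km_estimate([1, 2], [1, 1])
        lookup = dict(zip(t, s))
        assert lookup[1.0] == pytest.approx(0.5)
        assert lookup[2.0] == pytest.approx(0.0)

    def test_all_censored_flat(self):
        _, s = km_estimate([5, 8, 13], [0, 0, 0])
        assert np.all(s == 1.0)

    def test_hand_product_limit_with_censoring(self):
        t, s = km_estimate([1, 2, 3], [1, 0, 1])
        lookup = dict(zip(t, s))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(2 / 3)  # censoring does not drop
        assert lookup[3.0] == pytest.approx(0.0)

    def test_matches_hand_product_limit_random(self, rng):
        times = rng.integers(1, 20, size=30).astype(float)
        events = rng.integers(0, 2, size=30)
        t, s = km_estimate(times, events)
        # oracle: explicit product-limit over distinct event times
        surv = 1.0
        expected = {}
        for u in sorted(set(times)):
            at_risk = np.sum(times >= u)
            d = np.sum((times == u) & (events == 1))
            if d:
                surv *= 1 - d / at_risk
            expected[u] = surv
        lookup = dict(zip(t, s))
        for u, e in expected.items():
            assert lookup[u] == pytest.approx(e)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups(self):
        r = logrank([1, 2, 3, 4], [1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_clearly_separated_groups(self):
        a = np.arange(1.0, 11.0)
        b = a + 100.0
        r = logrank(a, np.ones(10, int), b, np.ones(10, int))
        assert r.p_value < 0.05

    def test_single_event_total(self):
        r = logrank([5.0, 7.0], [1, 0], [6.0, 8.0], [0, 0])
        assert np.isfinite(r.statistic)
        assert 0 <= r.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], [], [1.0], [1])
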