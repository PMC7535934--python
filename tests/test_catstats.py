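"""Unit and property tests for the contingency / two-group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from undeadlab import catstats
from undeadlab.catstats import (ContingencyTable, FamilySpec, ZeroMarginError,
                                bonferroni_adjust, exact_pearson_p,
                                expected_min, fisher_exact_2x2,
                                freeman_halton, mann_whitney_u,
                                pairwise_group_comparison, pearson_chi2,
                                ratio_of_pairs, two_group_decision_test)
from undeadlab.synthio import TwoGroupSpec, gen_two_group_samples

WALKING_GROUPS = [(1, 19), (13, 18), (2, 22), (9, 17)]


@st.composite
def random_2x2(draw):
    cells = [draw(st.integers(0, 15)) for _ in range(4)]
    t = np.array(cells).reshape(2, 2)
    # avoid zero margins so every test variant is defined
    t += np.eye(2, dtype=int)
    return t


class TestPearsonChi2:
    @pytest.mark.parametrize("table,expected", [
        ([[1, 18], [13, 5]], 17.6),
        ([[2, 20], [9, 8]], 9.1),
        ([[1, 18], [2, 20]], 0.2),
        ([[1, 18], [9, 8]], 10.2),
        ([[2, 20], [13, 5]], 16.8),
        ([[9, 8], [13, 5]], 1.4),
        ([[4, 2], [3, 1], [2, 5]], 2.9),
    ])
    def test_published_group_counts(self, table, expected):
        """Walked/not-walked count tables reproduce the reported statistics."""
        assert pearson_chi2(table).statistic == pytest.approx(expected,
                                                              abs=0.05)

    def test_proportional_rows_give_zero(self):
        assert pearson_chi2([[5, 5], [5, 5]]).statistic == 0.0

    def test_zero_margin_raises(self):
        with pytest.raises(ZeroMarginError):
            pearson_chi2([[0, 0], [3, 4]])

    @settings(deadline=None)
    @given(random_2x2())
    def test_permutation_invariance(self, t):
        base = pearson_chi2(t).statistic
        assert pearson_chi2(t[::-1]).statistic == pytest.approx(base)
        assert pearson_chi2(t[:, ::-1]).statistic == pytest.approx(base)


class TestExpectedCounts:
    @pytest.mark.parametrize("table,expected", [
        ([[1, 18], [13, 5]], 18 * 14 / 37),   # 6.81
        ([[2, 20], [9, 8]], 17 * 11 / 39),    # 4.79
        ([[10, 10], [10, 10]], 10.0),
    ])
    def test_min_expected(self, table, expected):
        assert expected_min(table) == pytest.approx(expected, abs=0.005)


class TestFisherExact:
    def test_uniform_2x2_is_modal(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p_raw == pytest.approx(1.0)

    def test_perfect_separation(self):
        # two extreme tables, each 1/C(10,5)
        res = fisher_exact_2x2([[0, 5], [5, 0]])
        assert res.p_raw == pytest.approx(2 / 252, rel=1e-9)

    def test_bonferroni_times_six_matches_published(self):
        p = fisher_exact_2x2([[2, 20], [9, 8]]).p_raw
        assert 6 * p == pytest.approx(0.0242, abs=5e-5)

    def test_zero_margin_flagged_p_one(self):
        res = fisher_exact_2x2([[0, 3], [0, 4]])
        assert res.p_raw == 1.0 and res.notes["zero_margin"]

    @settings(deadline=None, max_examples=60)
    @given(random_2x2())
    def test_matches_independent_hypergeometric_oracle(self, t):
        """Cross-check the enumeration against scipy's Fisher test."""
        assert fisher_exact_2x2(t).p_raw == pytest.approx(
            sstats.fisher_exact(t).pvalue, abs=1e-10)


class TestExactPearson:
    def test_published_adjusted_significance(self):
        res = exact_pearson_p([[1, 18], [13, 5]])
        assert res.p_raw <= 1e-4
        assert round(6 * res.p_raw, 4) == 0.0002

    def test_single_compatible_table(self):
        # margins [2,2]x[2,2] with counts [[2,0],[0,2]]... use a degenerate
        # margin: row [0, n] forces the whole table
        res = exact_pearson_p([[0, 3], [0, 4]])
        assert res.p_raw == 1.0

    def test_probabilities_sum_to_one(self):
        mass = catstats.enumerated_probability_mass([[4, 2], [3, 1], [2, 5]])
        assert mass == pytest.approx(1.0, abs=1e-9)

    def test_p_at_least_point_probability(self):
        t = ContingencyTable(np.array([[3, 7], [8, 2]]))
        p = exact_pearson_p(t).p_raw
        # point probability of the observed table: margins (10,10)x(11,9)
        point = sstats.hypergeom.pmf(3, 20, 10, 11)
        assert p >= point - 1e-12

    def test_guard_raises_beyond_limit(self):
        big = [[150, 30], [40, 60]]
        with pytest.raises(catstats.EnumerationGuardError):
            exact_pearson_p(big)

    def test_monte_carlo_fallback_close_to_enumeration(self, monkeypatch):
        monkeypatch.setattr(catstats, "MC_TABLES", 4000)
        t = [[12, 8], [7, 13]]
        exact = exact_pearson_p(t).p_raw
        monkeypatch.setattr(catstats, "ENUMERATION_GUARD", 10)
        mc = exact_pearson_p(t, rng=np.random.default_rng(0)).p_raw
        assert mc == pytest.approx(exact, abs=0.05)


class TestFreemanHalton:
    def test_published_3x2_both_orderings(self):
        """The reported subgroup exact p is reproduced by both tail rules."""
        for ordering in ("prob", "chi2"):
            p = freeman_halton([[4, 2], [3, 1], [2, 5]], ordering).p_raw
            assert p == pytest.approx(0.262855, abs=5e-7)

    def test_degenerate_margins_p_one(self):
        assert freeman_halton([[0, 2], [0, 3]]).p_raw == 1.0

    @settings(deadline=None, max_examples=60)
    @given(random_2x2())
    def test_reduces_to_fisher_on_2x2(self, t):
        assert freeman_halton(t).p_raw == pytest.approx(
            fisher_exact_2x2(t).p_raw, abs=1e-12)


class TestBonferroni:
    def test_uncapped_published_value(self):
        assert bonferroni_adjust(1.0, FamilySpec(k=6)) == 6.0

    def test_zero_stays_zero(self):
        assert bonferroni_adjust(0.0, FamilySpec(k=6)) == 0.0

    def test_capped_mode(self):
        assert bonferroni_adjust(0.5, FamilySpec(k=6, cap_at_one=True)) == 1.0

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 20))
    def test_linear_and_order_preserving(self, p1, p2, k):
        fam = FamilySpec(k=k)
        a1, a2 = bonferroni_adjust(p1, fam), bonferroni_adjust(p2, fam)
        assert a1 == pytest.approx(p1 * k)
        if p1 <= p2:
            assert a1 <= a2


class TestPairwiseComparison:
    def test_published_chi2_set(self):
        results = pairwise_group_comparison(WALKING_GROUPS)
        got = sorted(round(r.statistic, 1) for r in results)
        assert got == sorted([17.6, 0.2, 10.2, 16.8, 9.1, 1.4])

    def test_published_adjusted_p_values(self):
        """Every printed Bonferroni-adjusted p is reproduced exactly."""
        results = pairwise_group_comparison(WALKING_GROUPS)
        adj = {r.notes["pair"]: round(r.p_adjusted, 4) for r in results}
        assert adj[("group0", "group1")] == 0.0002
        assert adj[("group0", "group2")] == 6.0
        assert adj[("group0", "group3")] == 0.0135
        assert adj[("group1", "group2")] == 0.0002
        assert adj[("group1", "group3")] == 1.4283
        assert adj[("group2", "group3")] == 0.0242

    def test_identical_groups(self):
        results = pairwise_group_comparison([(5, 10), (5, 10)])
        assert results[0].statistic == 0.0
        assert results[0].p_adjusted == pytest.approx(1.0)  # k=1, p=1

    def test_family_size_is_pair_count(self):
        results = pairwise_group_comparison([(1, 5), (2, 5), (3, 5)])
        assert len(results) == 3
        assert all(r.notes["k"] == 3 for r in results)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_group_comparison([(0, 0), (1, 2)])


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        x, y = gen_two_group_samples(TwoGroupSpec("separated", n1=11, n2=11,
                                                  seed=0))
        assert mann_whitney_u(x, y).statistic == 0.0

    def test_minimal_samples(self):
        assert mann_whitney_u([1], [2]).statistic == 0.0

    def test_interleaved_brute_force(self):
        # pairs (x, y) with x > y: (3,2), (5,2), (5,4) -> U_y = 3 = min
        assert mann_whitney_u([1, 3, 5], [2, 4, 6]).statistic == 3.0

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=12,
                    unique=True))
    def test_u_bounds_and_complement(self, pool):
        half = len(pool) // 2 or 1
        x, y = np.array(pool[:half]), np.array(pool[half:] or [1001])
        u = mann_whitney_u(x, y).statistic
        n1n2 = x.size * y.size
        assert 0 <= u <= n1n2 / 2  # min(U1, U2) can never exceed half


class TestDecisionTree:
    @pytest.mark.parametrize("family,n,branch,min_count", [
        ("normal", 50, "t-test", 85),
        ("heteroscedastic-normal", 30, "welch", 85),
        ("heavy-tailed", 30, "mann-whitney", 95),
    ])
    def test_branch_selection_rates(self, family, n, branch, min_count):
        """Seeded simulation: the appropriate branch dominates.

        With a per-sample Lilliefors screen at alpha = 0.05, the two-sample
        pass probability is capped near 0.95^2 ~ 0.90; the frozen seeds
        measure 88 (t-test), 87 (Welch) and 100 (Mann-Whitney) per 100.
        """
        hits = 0
        for seed in range(100):
            x, y = gen_two_group_samples(TwoGroupSpec(family, n1=n, n2=n,
                                                      seed=seed))
            if two_group_decision_test(x, y).branch_taken == branch:
                hits += 1
        assert hits >= min_count

    def test_small_sample_fallback_warns(self):
        with pytest.warns(UserWarning):
            res = two_group_decision_test([1.0, 2.0], [3.0, 4.0])
        assert "mann-whitney" in res.branch_taken


class TestRatioOfPairs:
    def test_identical_vectors(self):
        res = ratio_of_pairs([2, 3, 4], [2, 3, 4])
        assert res["mean"] == 1.0 and res["sd"] == 0.0

    def test_scaling_numerator(self):
        base = ratio_of_pairs([2, 3, 4], [1, 2, 3])
        doubled = ratio_of_pairs([4, 6, 8], [1, 2, 3])
        assert doubled["mean"] == pytest.approx(2 * base["mean"])

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(5)
        num, den = rng.uniform(1, 10, 30), rng.uniform(1, 10, 30)
        res = ratio_of_pairs(num, den)
        assert res["mean"] == pytest.approx((num / den).mean())
        assert res["sd"] == pytest.approx((num / den).std(ddof=1))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ratio_of_pairs([1, 2], [1, 0])


class TestNullCalibration:
    def test_fisher_conservative_under_null(self):
        """Exact tests reject at most at nominal level under the null."""
        rng = np.random.default_rng(2024)
        n, p_true, alpha = 20, 0.3, 0.05
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a, b = rng.binomial(n, p_true, 2)
            p = fisher_exact_2x2([[a, n - a], [b, n - b]]).p_raw
            if p < alpha:
                rejections += 1
        assert rejections / reps <= alpha
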