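from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refreo import (
    aging_genes,
    bh_adjust,
    binomial_consistency,
    fisher_2x2,
    hypergeom_overlap,
    ttest_degs,
    wilcoxon_rank_sum,
)

from conftest import make_matrix


class TestBhAdjust:
    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.7]), [0.7])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        got = bh_adjust(p)
        want = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_order_invariant_and_monotone(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))
        order = np.argsort(p)
        adj = bh_adjust(p)[order]
        assert np.all(np.diff(adj) >= -1e-15)
        assert np.all(adj <= 1)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestTtestDegs:
    def test_identical_groups_p_one(self):
        values = np.tile([[5.0]], (1, 6))
        m = make_matrix(values, group=["control"] * 3 + ["case"] * 3)
        out = ttest_degs(m)
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[0, "t"] == 0.0

    def test_closed_form_example(self):
        m = make_matrix([[1, 2, 3, 4, 5, 6]],
                        group=["case"] * 3 + ["control"] * 3)
        out = ttest_degs(m)
        assert out.loc[0, "t"] == pytest.approx(-3.674234614, rel=1e-6)
        assert out.loc[0, "p"] == pytest.approx(0.021311641, rel=1e-6)
        assert out.loc[0, "direction"] == -1

    def test_power_of_planted_shift(self):
        """3-within-sd shift at n=10+10 is detected at FDR 5% nearly always."""
        detected = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ctrl = rng.normal(0, 1, size=(1, 10))
            case = rng.normal(3, 1, size=(1, 10))
            m = make_matrix(np.concatenate([ctrl, case], axis=1),
                            group=["control"] * 10 + ["case"] * 10)
            detected += int(ttest_degs(m)["is_deg"].iloc[0])
        assert detected >= 95

    def test_null_fdr_controlled(self):
        """On pure-noise data the empirical FDR stays near nominal."""
        false_calls = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            m = make_matrix(rng.normal(size=(50, 20)),
                            group=["control"] * 10 + ["case"] * 10)
            false_calls += int(ttest_degs(m)["is_deg"].sum())
        # any call is false here; FDR 0.05 over 100 seeds x 50 genes
        assert false_calls <= 0.05 * 1.5 * 100 * 50


class TestAgingGenes:
    def test_perfect_linear_fit(self):
        ages = np.array([50.0, 60.0, 70.0, 80.0])
        m = make_matrix((2 * ages)[None, :], age=ages)
        out = aging_genes(m)
        assert out.loc[0, "slope"] == pytest.approx(2.0)
        assert out.loc[0, "p"] < 1e-10

    def test_constant_expression(self):
        ages = np.array([50.0, 60.0, 70.0, 80.0])
        m = make_matrix(np.full((1, 4), 3.0), age=ages)
        out = aging_genes(m)
        assert out.loc[0, "slope"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_constant_age_errors(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(3, 4)),
                        age=[60.0] * 4)
        with pytest.raises(ValueError, match="constant"):
            aging_genes(m)

    def test_null_p_uniform(self, rng):
        """Age-independent expression: ~5% of genes below p 0.05."""
        ages = rng.uniform(50, 90, size=40)
        m = make_matrix(rng.normal(size=(2000, 40)), age=ages)
        out = aging_genes(m)
        frac = (out["p"] < 0.05).mean()
        assert 0.03 < frac < 0.08
        assert not out["is_significant"].any()

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        ages = rng.uniform(50, 90, size=15)
        y = 0.05 * ages + rng.normal(size=15)
        m = make_matrix(y[None, :], age=ages)
        out = aging_genes(m)
        fit = sm.OLS(y, sm.add_constant(ages)).fit()
        assert out.loc[0, "slope"] == pytest.approx(fit.params[1], rel=1e-10)
        assert out.loc[0, "p"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_planted_slopes_recovered(self):
        """50 of 1000 genes with slopes well above noise: high recall, low FDR."""
        rng = np.random.default_rng(7)
        n, n_samp = 1000, 60
        ages = rng.uniform(50, 90, size=n_samp)
        values = rng.normal(size=(n, n_samp))
        slopes = np.zeros(n)
        slopes[:50] = rng.choice([-1, 1], 50) * 0.05  # sd/decade ~ 0.5 noise sd
        values += slopes[:, None] * (ages - ages.mean())[None, :]
        m = make_matrix(values, age=ages)
        out = aging_genes(m)
        called = set(out.index[out["is_significant"]])
        true = set(range(50))
        recall = len(called & true) / 50
        fdr = len(called - true) / max(len(called), 1)
        assert recall >= 0.7
        assert fdr <= 0.1


def overlap_enumeration(N, K, n, k):
    marked = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n)
               if len(marked & set(draw)) >= k)
    return hits / comb(N, n)


class TestHypergeomOverlap:
    def test_toy_enumeration_value(self):
        assert hypergeom_overlap(10, 4, 3, 2).p == pytest.approx(1 / 3, rel=1e-12)

    def test_zero_overlap_is_one(self):
        assert hypergeom_overlap(100, 10, 5, 0).p == pytest.approx(1.0)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 4, 3, 4)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_enumeration_small(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(2, 12))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        got = hypergeom_overlap(N, K, n, k).p
        assert got == pytest.approx(overlap_enumeration(N, K, n, k), rel=1e-9)


class TestBinomialConsistency:
    def test_all_consistent(self):
        assert binomial_consistency(21, 21) == pytest.approx(0.5 ** 21, rel=1e-12)

    def test_single_trial(self):
        assert binomial_consistency(1, 1) == pytest.approx(0.5)

    def test_zero_consistent(self):
        assert binomial_consistency(0, 5) == pytest.approx(1.0)

    def test_zero_trials_error(self):
        with pytest.raises(ValueError):
            binomial_consistency(0, 0)


class TestWilcoxon:
    def test_exact_most_extreme_split(self):
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_multisets(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_symmetry_under_label_swap(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(0.5, 1, size=15)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))

    def test_all_identical_values(self):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5]) == 1.0

    def test_exact_matches_enumeration(self):
        """Two-sided exact p equals the rank-split enumeration oracle."""
        x = [1.0, 4.0, 6.0]
        y = [2.0, 3.0, 5.0, 7.0]
        got = wilcoxon_rank_sum(x, y)
        # enumerate all C(7,3) assignments of ranks to group x
        ranks = range(1, 8)
        obs = sum([1, 4, 6])  # x holds ranks 1, 4, 6
        stats = [sum(c) for c in combinations(ranks, 3)]
        mean = np.mean(stats)
        extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-9)
        assert got == pytest.approx(extreme / len(stats), rel=1e-9)


class TestFisher2x2:
    def test_two_sided_enumeration_value(self):
        assert fisher_2x2(10, 0, 5, 5) == pytest.approx(6006 / 184756, rel=1e-10)

    def test_identical_rows(self):
        assert fisher_2x2(4, 6, 4, 6) == pytest.approx(1.0)

    def test_directional_one_sided_leq_two_sided(self, rng):
        # the one-sided tail in the direction of the observed deviation
        # (the smaller of the two tails) never exceeds the two-sided p
        for _ in range(20):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            directional = min(fisher_2x2(a, b, c, d, sided="one"),
                              fisher_2x2(c, d, a, b, sided="one"))
            assert directional <= fisher_2x2(a, b, c, d, sided="two") + 1e-12

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            fisher_2x2(0, 0, 0, 0)
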