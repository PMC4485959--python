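"""Pagel's lambda estimation, Moran's I and correlogram machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phylofd import (
    bm_loglik,
    build_distance_classes,
    fit_lambda,
    lambda_transform,
    moran_i,
    parametric_bootstrap_ci,
    patristic_distances,
    phylo_correlogram,
    phylo_vcv,
    read_newick,
    simulate_bm_trait,
    simulate_two_clade_tree,
    simulate_yule_tree,
)
from phylofd.treeio import LAMBDA_EPS

from conftest import brute_force_moran


class TestBmLoglik:
    def test_single_tip_standard_normal_at_mode(self):
        V = pd.DataFrame([[1.0]], index=["A"], columns=["A"])
        ll = bm_loglik(np.array([0.0]), V, sigma2=1.0, z0=0.0)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_star_tree_equals_iid_normal(self, star4):
        V = phylo_vcv(star4)
        x = np.array([0.3, -1.2, 0.7, 2.0])
        ll = bm_loglik(x, V, sigma2=1.5, z0=0.2)
        iid = stats.norm.logpdf(x, loc=0.2, scale=np.sqrt(1.5)).sum()
        assert ll == pytest.approx(iid, abs=1e-10)

    def test_matches_dense_mvn_oracle(self):
        tree = simulate_yule_tree(5, seed=9)
        V = phylo_vcv(tree)
        rng = np.random.default_rng(1)
        x = rng.normal(size=5)
        ll = bm_loglik(x, V, sigma2=0.8, z0=0.1)
        oracle = stats.multivariate_normal.logpdf(
            x, mean=np.full(5, 0.1), cov=0.8 * V.to_numpy()
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_invariant_under_tip_relabeling(self):
        tree = simulate_yule_tree(8, seed=10)
        V = phylo_vcv(tree)
        x = pd.Series(np.random.default_rng(2).normal(size=8), index=V.index)
        perm = list(reversed(V.index))
        Vp = V.loc[perm, perm]
        assert bm_loglik(x, V, 1.0, 0.0) == pytest.approx(
            bm_loglik(x.loc[perm], Vp, 1.0, 0.0), abs=1e-10
        )

    def test_nonpositive_sigma2_rejected(self, star4):
        with pytest.raises(ValueError):
            bm_loglik(np.zeros(4), phylo_vcv(star4), sigma2=0.0, z0=0.0)


class TestFitLambda:
    def test_profile_matches_dense_loglik_at_optimum(self):
        # cross-check the O(n) eigendecomposition path against the dense
        # Cholesky likelihood at the fitted parameters
        tree = simulate_yule_tree(30, seed=3)
        x = simulate_bm_trait(tree, sigma2=2.0, lambda_true=0.7, seed=4)
        fit = fit_lambda(x, tree)
        V_lam = lambda_transform(phylo_vcv(tree), fit.lambda_hat)
        dense = bm_loglik(x, V_lam, fit.sigma2_hat, fit.z0_hat)
        assert fit.loglik == pytest.approx(dense, abs=1e-8)

    def test_constant_trait_rejected(self, yule10):
        with pytest.raises(ValueError, match="constant"):
            fit_lambda(np.ones(10), yule10)

    def test_non_ultrametric_rejected(self):
        tree = read_newick("((A:1,B:2):1,(C:1,D:1):2);")
        with pytest.raises(ValueError, match="ultrametric"):
            fit_lambda(np.array([1.0, 2.0, 3.0, 4.0]), tree)

    def test_too_few_tips_rejected(self, three_tip):
        with pytest.raises(ValueError, match="4 tips"):
            fit_lambda(np.array([1.0, 2.0, 3.0]), three_tip)

    def test_iid_trait_estimates_near_zero(self):
        tree = simulate_yule_tree(100, seed=5)
        x = pd.Series(
            np.random.default_rng(6).normal(size=100), index=tree.tip_labels
        )
        fit = fit_lambda(x, tree)
        assert fit.lambda_hat < 0.15

    def test_bm_trait_estimates_near_one(self):
        tree = simulate_yule_tree(100, seed=7)
        x = simulate_bm_trait(tree, sigma2=1.0, lambda_true=1.0, seed=8)
        assert fit_lambda(x, tree).lambda_hat > 0.85

    def test_estimate_within_bounds_and_sigma_positive(self, yule61, bm_trait):
        fit = fit_lambda(bm_trait, yule61)
        assert LAMBDA_EPS <= fit.lambda_hat <= 1.0
        assert fit.sigma2_hat > 0


class TestBootstrapCI:
    def test_deterministic_given_seed(self, yule61, bm_trait):
        fit = fit_lambda(bm_trait, yule61)
        a = parametric_bootstrap_ci(fit, yule61, n_sim=50, seed=123)
        b = parametric_bootstrap_ci(fit, yule61, n_sim=50, seed=123)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_brackets_estimate(self, yule61, bm_trait):
        fit = fit_lambda(bm_trait, yule61)
        out = parametric_bootstrap_ci(fit, yule61, n_sim=100, seed=1)
        assert LAMBDA_EPS <= out.ci_low <= fit.lambda_hat <= out.ci_high <= 1.0
        assert out.n_boot == 100

    def test_near_zero_signal_ci_floor_at_eps(self):
        # a trait with no phylogenetic structure: lower CI bound collapses
        # to the epsilon bound of the lambda domain
        tree = simulate_yule_tree(60, seed=20)
        x = pd.Series(np.random.default_rng(21).normal(size=60), index=tree.tip_labels)
        fit = fit_lambda(x, tree)
        out = parametric_bootstrap_ci(fit, tree, n_sim=100, seed=22)
        assert out.ci_low <= 5 * LAMBDA_EPS


class TestMoranI:
    def test_two_tips_always_minus_one(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        for vals in ([1.0, 5.0], [-2.0, 0.3]):
            res = moran_i(np.array(vals), W, n_perm=19, seed=0)
            assert res.I == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 26))
        x = rng.normal(size=n)
        W = (rng.random((n, n)) < 0.4).astype(float)
        W = np.triu(W, 1)
        W = W + W.T
        if W.sum() == 0:
            W[0, 1] = W[1, 0] = 1.0
        res = moran_i(x, W, n_perm=9, seed=0)
        assert res.I == pytest.approx(brute_force_moran(x, W), abs=1e-12)

    def test_permutation_null_mean_near_expected(self):
        rng = np.random.default_rng(1)
        n = 20
        W = np.ones((n, n)) - np.eye(n)
        # under pure shuffling the mean of I across many null draws
        # approaches -1/(n-1)
        vals = [
            moran_i(rng.normal(size=n), W, n_perm=9, seed=0).I for _ in range(500)
        ]
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.02)

    def test_constant_trait_rejected(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="constant"):
            moran_i(np.array([2.0, 2.0]), W)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            moran_i(np.array([1.0, 2.0]), np.zeros((2, 2)))

    def test_normal_approximation_agrees_in_direction(self):
        tree = simulate_two_clade_tree(30, seed=2)
        x = simulate_bm_trait(tree, lambda_true=1.0, seed=3)
        D = patristic_distances(tree)
        _, weights = build_distance_classes(D, n_classes=4)
        perm = moran_i(x.to_numpy(), weights[0], n_perm=999, seed=4)
        norm = moran_i(x.to_numpy(), weights[0], method="normal")
        assert perm.I == norm.I
        assert (perm.p_value < 0.05) == (norm.p_value < 0.05)

    def test_minimum_p_with_999_permutations(self):
        # strong positive autocorrelation saturates the permutation floor
        tree = simulate_two_clade_tree(40, seed=5)
        x = simulate_bm_trait(tree, lambda_true=1.0, seed=6)
        D = patristic_distances(tree)
        _, weights = build_distance_classes(D, n_classes=2)
        res = moran_i(x.to_numpy(), weights[-1], n_perm=999, seed=7)
        assert res.p_value >= 1 / 1000


class TestDistanceClasses:
    def test_two_depth_tree_has_two_nonempty_classes(self):
        # distances are only 2 and 4: of 8 equal-width classes exactly 2
        # can hold pairs
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        D = patristic_distances(tree)
        with pytest.warns(UserWarning, match="empty"):
            _, weights = build_distance_classes(D, n_classes=8)
        non_empty = sum(1 for W in weights if W.sum() > 0)
        assert non_empty == 2

    def test_classes_partition_all_pairs(self, yule61):
        D = patristic_distances(yule61)
        spec, weights = build_distance_classes(D, n_classes=8)
        total = sum(W for W in weights)
        n = yule61.n_tips
        np.testing.assert_allclose(total, np.ones((n, n)) - np.eye(n))
        assert sum(int(W.sum() / 2) for W in weights) == n * (n - 1) // 2

    def test_equal_frequency_balances_counts_when_distances_distinct(self):
        # with all-distinct distances, quantile cuts give class pair-counts
        # differing by at most 1
        rng = np.random.default_rng(8)
        n = 25
        M = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        M[iu] = rng.permutation(np.arange(1, len(iu[0]) + 1, dtype=float))
        M = M + M.T
        D = pd.DataFrame(M, index=range(n), columns=range(n))
        _, weights = build_distance_classes(D, n_classes=8, scheme="equal_frequency")
        counts = [int(W.sum() / 2) for W in weights]
        assert max(counts) - min(counts) <= 1

    def test_equal_frequency_on_tree_collapses_only_at_ties(self, yule61):
        # tree distances come in tie blocks (pairs sharing an MRCA are
        # equidistant); classes never split a tie block, and every pair is
        # still covered exactly once
        D = patristic_distances(yule61)
        n = yule61.n_tips
        with pytest.warns(UserWarning, match="tied"):
            _, weights = build_distance_classes(
                D, n_classes=8, scheme="equal_frequency"
            )
        assert sum(int(W.sum() / 2) for W in weights) == n * (n - 1) // 2
        Dv = D.to_numpy()
        for W in weights:
            covered = Dv[W.astype(bool)]
            others = Dv[np.triu(~W.astype(bool), 1).astype(bool)]
            assert not (set(covered) & set(others[others > 0]))

    def test_bounds_strictly_increasing(self, yule61):
        spec, _ = build_distance_classes(patristic_distances(yule61), n_classes=8)
        assert (np.diff(spec.bounds) > 0).all()
        assert spec.bounds[0] == 0.0


class TestCorrelogram:
    def test_empty_classes_flagged(self):
        tree = read_newick("((A:1,B:1):9,(C:1,D:1):9);")
        x = pd.Series([0.1, 0.2, 5.0, 5.3], index=["A", "B", "C", "D"])
        with pytest.warns(UserWarning):
            corr = phylo_correlogram(x, tree, n_classes=8, n_perm=99, seed=0)
        assert corr["empty"].sum() == 6
        assert corr.loc[corr["empty"], "I"].isna().all()
        assert len(corr) == 8

    def test_deterministic_given_seed(self, yule61, bm_trait):
        a = phylo_correlogram(bm_trait, yule61, n_perm=99, seed=5)
        b = phylo_correlogram(bm_trait, yule61, n_perm=99, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_pair_counts_partition(self, yule61, bm_trait):
        corr = phylo_correlogram(bm_trait, yule61, n_perm=9, seed=1)
        n = yule61.n_tips
        assert corr["n_pairs"].sum() == n * (n - 1) // 2

    def test_shallow_signal_positive_at_smallest_class(self):
        tree = simulate_two_clade_tree(61, seed=30)
        x = simulate_bm_trait(tree, lambda_true=1.0, seed=31)
        corr = phylo_correlogram(x, tree, n_perm=999, seed=32)
        first = corr[~corr["empty"]].iloc[0]
        assert first["I"] > 0
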