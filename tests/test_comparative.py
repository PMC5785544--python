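"""Tree-aware machinery: contrasts, squared-change parsimony, K, BM."""

import numpy as np
import pytest
from scipy.optimize import minimize

from phylomorph import (Phylogeny, TreeError, ancestors_scp,
                        evolutionary_rate_matrix, map_size_evolution, pca,
                        physignal_K, pic, pure_birth_tree, simulate_bm)
from phylomorph.comparative import bm_tip_simulator


def pic_oracle(tree, Y):
    """Independent recursive implementation of the contrast algorithm,
    written directly from the published recursion (dict-based, no shared
    code with the package implementation)."""
    Y = np.atleast_2d(Y)
    vals = {i: Y[i].astype(float) for i in range(tree.n_tips)}
    lens = {i: float(tree.lengths[i]) for i in range(tree.n_nodes)}
    out = []
    for nd in tree.postorder():
        if nd < tree.n_tips:
            continue
        c1, c2 = tree.children[nd]
        b1, b2 = lens[c1], lens[c2]
        out.append((vals[c1] - vals[c2]) / np.sqrt(b1 + b2))
        vals[nd] = (b2 * vals[c1] + b1 * vals[c2]) / (b1 + b2)
        lens[nd] = lens[nd] + b1 * b2 / (b1 + b2)
    return np.asarray(out)


class TestPIC:
    def test_two_tip_closed_form(self):
        t = Phylogeny.from_newick("(A:1,B:1);", is_path=False)
        u = pic(t, [[0.0], [1.0]])
        assert abs(abs(u[0, 0]) - 1 / np.sqrt(2)) < 1e-12

    def test_identical_values_zero_contrasts(self, small_tree):
        u = pic(small_tree, np.full((5, 3), 2.5))
        assert np.abs(u).max() == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_recursion(self, seed):
        tree = pure_birth_tree(8, seed=seed)
        Y = np.random.default_rng(seed).standard_normal((8, 4))
        assert np.abs(pic(tree, Y) - pic_oracle(tree, Y)).max() < 1e-10

    def test_name_mismatch_lists_absentees(self, small_tree):
        with pytest.raises(TreeError, match="E"):
            pic(small_tree, np.zeros((4, 1)), names=["A", "B", "C", "D"])

    def test_contrasts_iid_under_bm(self):
        """Standardized contrasts of a BM trait have unit variance given a
        unit evolutionary rate."""
        tree = pure_birth_tree(64, seed=5)
        Y = simulate_bm(tree, np.eye(400), seed=6)   # 400 replicate traits
        u = pic(tree, Y)
        assert np.var(u) == pytest.approx(1.0, rel=0.1)


class TestSquaredChangeParsimony:
    def test_two_tip_weighted_closed_form(self):
        t = Phylogeny.from_newick("(A:1,B:3);", is_path=False)
        est = ancestors_scp(t, [[0.0], [1.0]], mode="weighted")
        assert est.node_values[0, 0] == pytest.approx(0.25)

    def test_constant_trait_constant_everywhere(self, small_tree):
        for mode in ("weighted", "unweighted"):
            est = ancestors_scp(small_tree, np.full((5, 2), 7.0), mode=mode)
            assert np.allclose(est.node_values, 7.0)

    def test_matches_numerical_minimizer(self):
        """Weighted estimates equal direct numerical minimization of the
        weighted sum of squared changes (general-purpose optimizer)."""
        tree = pure_birth_tree(6, seed=11)
        Y = np.random.default_rng(11).standard_normal((6, 2))
        est = ancestors_scp(tree, Y, mode="weighted")
        m = tree.n_nodes - tree.n_tips

        def objective(x):
            states = np.vstack([Y, x.reshape(m, 2)])
            total = 0.0
            for nd in range(tree.n_nodes):
                par = tree.parent[nd]
                if par < 0:
                    continue
                total += ((states[nd] - states[par]) ** 2).sum() \
                    / tree.lengths[nd]
            return total

        x0 = np.tile(Y.mean(axis=0), m)
        opt = minimize(objective, x0, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        assert np.abs(est.node_values - opt.x.reshape(m, 2)).max() < 1e-6

    def test_unweighted_star_tree_estimates_in_hull(self):
        star = Phylogeny(np.array([4, 4, 4, 4, -1]),
                         np.array([1.0, 1, 1, 1, 0]),
                         ["a", "b", "c", "d"])
        Y = np.array([[0.0], [1.0], [2.0], [5.0]])
        est = ancestors_scp(star, Y, mode="unweighted")
        assert Y.min() <= est.node_values[0, 0] <= Y.max()

    def test_weighted_root_invariant_to_rerooting_position(self):
        """On an ultrametric tree the weighted (ML) root estimate is stable
        when the root branch is subdivided by a zero-change node."""
        t1 = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);",
                                   is_path=False)
        t2 = Phylogeny.from_newick("(((A:1,B:1):0.5):0.5,(C:1,D:1):1);",
                                   is_path=False)
        Y = np.array([[0.0], [2.0], [3.0], [7.0]])
        r1 = ancestors_scp(t1, Y, mode="weighted").node_values[-1]
        r2 = ancestors_scp(t2, Y, mode="weighted").node_values[-1]
        assert np.allclose(r1, r2, atol=1e-9)

    def test_polytomy_resolved_automatically(self):
        t = Phylogeny.from_newick("(A:1,B:1,C:1,D:1);", is_path=False)
        est = ancestors_scp(t, [[0.0], [1.0], [2.0], [3.0]], mode="weighted")
        assert np.isfinite(est.node_values).all()


class TestMapSizeEvolution:
    def test_equal_sizes_constant(self, small_tree):
        est = map_size_evolution(small_tree, np.full(5, 4.2))
        assert np.allclose(est.node_values, 4.2)

    def test_planted_decrease_gives_intermediate_mrca(self):
        tree = Phylogeny.from_newick(
            "((A:1,B:1):1,(C:1,D:1):1);", is_path=False)
        sizes = np.array([10.0, 10.0, 1.0, 1.0])   # C,D miniaturized
        est = map_size_evolution(tree, sizes,
                                 names=["A", "B", "C", "D"])
        mrca_cd = tree.mrca(["C", "D"])
        val = est.all_values[mrca_cd, 0]
        root = est.all_values[tree.root, 0]
        assert 1.0 < val < root

    def test_matches_shape_code_path_q1(self, small_tree, rng):
        sizes = np.exp(rng.standard_normal(5))
        est = map_size_evolution(small_tree, sizes)
        shp = ancestors_scp(small_tree, np.log(sizes)[:, None],
                            mode="weighted")
        assert np.allclose(est.node_values, np.exp(shp.node_values))

    def test_nonpositive_sizes_rejected(self, small_tree):
        with pytest.raises(ValueError, match="positive"):
            map_size_evolution(small_tree, [1.0, 2.0, -1.0, 1.0, 1.0])


class TestPhyloSignalK:
    def test_brownian_expectation_near_one(self):
        tree = pure_birth_tree(64, seed=2)
        rng = np.random.default_rng(3)
        Ks = []
        for _ in range(40):
            Y = simulate_bm(tree, np.eye(3), seed=rng.integers(2**31))
            Ks.append(physignal_K(tree, Y, n_perm=9, seed=0).K)
        assert 0.85 < np.mean(Ks) < 1.15

    def test_shuffled_data_low_K_high_p(self):
        tree = pure_birth_tree(48, seed=4)
        rng = np.random.default_rng(5)
        Ks, ps = [], []
        for _ in range(20):
            Y = simulate_bm(tree, np.eye(3), seed=rng.integers(2**31))
            Y = Y[rng.permutation(48)]
            r = physignal_K(tree, Y, n_perm=99, seed=int(rng.integers(2**31)))
            Ks.append(r.K)
            ps.append(r.p_value)
        assert np.mean(ps) > 0.2

    def test_bm_signal_detected(self):
        tree = pure_birth_tree(64, seed=6)
        Y = simulate_bm(tree, np.eye(4), seed=7)
        r = physignal_K(tree, Y, n_perm=199, seed=8)
        assert r.p_value <= 0.05

    def test_zero_variance_rejected(self, small_tree):
        with pytest.raises(ValueError, match="variance"):
            physignal_K(small_tree, np.ones((5, 2)))

    def test_needs_four_tips(self):
        t = Phylogeny.from_newick("(A:1,(B:1,C:1):1);", is_path=False)
        with pytest.raises(TreeError):
            physignal_K(t, np.random.default_rng(0).standard_normal((3, 2)))


class TestSimulateBM:
    def test_zero_rate_all_tips_at_root(self, small_tree):
        Y = simulate_bm(small_tree, np.zeros((2, 2)), root=[1.0, -2.0],
                        seed=0)
        assert np.allclose(Y, [1.0, -2.0])

    def test_tip_variance_matches_theory(self):
        t = Phylogeny.from_newick("(A:1.5,B:0.5);", is_path=False)
        Y = simulate_bm(t, np.eye(2000), seed=1)  # replicate traits
        vA = np.var(Y[0])
        vB = np.var(Y[1])
        assert vA == pytest.approx(1.5, rel=0.1)
        assert vB == pytest.approx(0.5, rel=0.1)

    def test_sister_covariance_matches_shared_path(self):
        t = Phylogeny.from_newick("((A:1,B:1):2,C:3);", is_path=False)
        Y = simulate_bm(t, np.eye(4000), seed=2)
        cov_ab = np.mean(Y[0] * Y[1])
        assert cov_ab == pytest.approx(2.0, rel=0.1)

    def test_non_psd_rate_rejected(self, small_tree):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="semidefinite"):
            simulate_bm(small_tree, bad)

    def test_fast_simulator_matches_covariance(self):
        tree = pure_birth_tree(16, seed=3)
        draw = bm_tip_simulator(tree, np.eye(1))
        rng = np.random.default_rng(4)
        Y = np.hstack([draw(rng) for _ in range(3000)])
        C = tree.vcv()
        emp = (Y @ Y.T) / Y.shape[1]
        assert np.abs(emp - C).max() < 0.15 * C.max()


class TestRateMatrix:
    def test_recovers_generating_covariance(self):
        tree = pure_birth_tree(200, seed=9)
        R = np.array([[1.0, 0.6], [0.6, 2.0]])
        Y = simulate_bm(tree, R, seed=10)
        est = evolutionary_rate_matrix(tree, Y)
        assert np.abs(est - R).max() < 0.5


class TestPhylomorphospaceCommutation:
    def test_ancestors_commute_with_pca_projection(self):
        """Ancestral estimation is linear, so SCP of PC scores equals the
        PCA projection of SCP ancestors of the raw data."""
        tree = pure_birth_tree(24, seed=12)
        Y = simulate_bm(tree, np.eye(6), seed=13)
        ms = pca(Y)
        anc_raw = ancestors_scp(tree, Y, mode="weighted").node_values
        anc_scores = ancestors_scp(tree, ms.scores,
                                   mode="weighted").node_values
        assert np.abs(ms.project(anc_raw) - anc_scores).max() < 1e-8
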