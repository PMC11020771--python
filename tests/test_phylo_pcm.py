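"""Newick handling, BM covariance, phylogenetic signal, PGLS, BM simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from craniomech import phylo_pcm as pp
from craniomech import synthetic_data as synth


class TestNewick:
    def test_three_tip_depths(self):
        t = pp.tree_from_string("((A:1,B:1):1,C:2);")
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert t.depths().round(9).tolist() == [2.0, 2.0, 2.0]

    def test_round_trip(self, tmp_path, tree32):
        path = tmp_path / "t.nwk"
        pp.write_newick(tree32, path)
        back = pp.read_newick(path)
        assert back.tip_labels == tree32.tip_labels
        pd.testing.assert_series_equal(back.depths(), tree32.depths(),
                                       atol=1e-9)
        c1 = pp.bm_covariance(tree32).to_numpy()
        c2 = pp.bm_covariance(back).to_numpy()
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_malformed_parenthesis_raises(self):
        with pytest.raises(ValueError, match="[Nn]ewick|[Pp]ars"):
            pp.tree_from_string("((A:1,B:1:1,C:2);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pp.tree_from_string("((A:1,A:1):1,C:2);")


class TestBMCovariance:
    def test_star_tree_is_scaled_identity(self):
        t = pp.tree_from_string("(A:3,B:3,C:3,D:3);")
        c = pp.bm_covariance(t).to_numpy()
        np.testing.assert_allclose(c, 3 * np.eye(4), atol=1e-12)

    def test_shared_path_lengths(self):
        c = pp.bm_covariance(pp.tree_from_string("((A:1,B:1):1,C:2);"))
        assert c.loc["A", "B"] == pytest.approx(1.0)
        assert c.loc["A", "A"] == pytest.approx(2.0)
        assert c.loc["A", "C"] == pytest.approx(0.0)

    def test_matches_mrca_path_enumeration_oracle(self):
        """Random trees vs a brute-force MRCA depth computation."""
        for seed in (2, 5, 9):
            tree = synth.pure_birth_tree(10, seed=seed)
            c = pp.bm_covariance(tree)
            # oracle: common prefix of root-to-tip edge paths
            paths = {}
            for leaf in tree.tree.leaf_node_iter():
                path = []
                node = leaf
                while node.parent_node is not None:
                    path.append(node)
                    node = node.parent_node
                paths[leaf.taxon.label] = list(reversed(path))
            for i in c.index:
                for j in c.columns:
                    shared = 0.0
                    for a, b in zip(paths[i], paths[j]):
                        if a is b:
                            shared += a.edge.length
                        else:
                            break
                    assert c.loc[i, j] == pytest.approx(shared, abs=1e-9)

    def test_psd(self, tree32):
        c = pp.bm_covariance(tree32).to_numpy()
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        w = np.linalg.eigvalsh(c)
        assert w.min() > -1e-10


class TestPhylogeneticSignal:
    def test_bm_calibration_mean_near_one(self, tree32):
        ks = [pp.blomberg_k(tree32, pp.simulate_bm(tree32, seed=100 + i).iloc[:, 0],
                            n_perm=0).statistic
              for i in range(200)]
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_kmult_bm_calibration(self, tree32):
        km = [pp.kmult(tree32, pp.simulate_bm(tree32, n_traits=5, seed=500 + i),
                       n_perm=0).statistic
              for i in range(200)]
        assert 0.9 <= np.mean(km) <= 1.1

    def test_univariate_kmult_equals_blomberg_k(self, tree32):
        tr = pp.simulate_bm(tree32, seed=7)
        a = pp.kmult(tree32, tr, n_perm=9, seed=3)
        b = pp.blomberg_k(tree32, tr.iloc[:, 0], n_perm=9, seed=3)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)
        assert a.p_value == b.p_value

    def test_seed_determinism(self, tree32):
        tr = pp.simulate_bm(tree32, seed=11).iloc[:, 0]
        a = pp.blomberg_k(tree32, tr, n_perm=99, seed=42)
        b = pp.blomberg_k(tree32, tr, n_perm=99, seed=42)
        assert a.p_value == b.p_value
        assert a.p_value in {k / 100 for k in range(1, 101)}

    def test_affine_invariance(self, tree32):
        tr = pp.simulate_bm(tree32, seed=13).iloc[:, 0]
        base = pp.blomberg_k(tree32, tr, n_perm=0).statistic
        moved = pp.blomberg_k(tree32, 3.5 * tr - 11.0, n_perm=0).statistic
        assert moved == pytest.approx(base, rel=1e-9)

    def test_null_p_values_roughly_uniform(self, tree32):
        """Tip-shuffled (signal-free) data yields approximately uniform
        permutation p-values."""
        rng = np.random.default_rng(0)
        ps = []
        for i in range(200):
            vals = rng.standard_normal(32)  # exchangeable across tips
            tr = pd.Series(vals, index=tree32.tip_labels)
            ps.append(pp.blomberg_k(tree32, tr, n_perm=49,
                                    seed=int(rng.integers(2 ** 31))).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_trait_rejected(self, tree32):
        tr = pd.Series(1.0, index=tree32.tip_labels)
        with pytest.raises(ValueError, match="constant"):
            pp.blomberg_k(tree32, tr, n_perm=9)

    def test_label_mismatch_rejected(self, tree32):
        tr = pd.Series(np.arange(5.0), index=list("ABCDE"))
        with pytest.raises(ValueError, match="missing"):
            pp.blomberg_k(tree32, tr, n_perm=9)


class TestPGLS:
    def test_star_tree_equals_ols(self):
        star = pp.tree_from_string("(A:2,B:2,C:2,D:2,E:2,F:2,G:2);")
        rng = np.random.default_rng(4)
        labels = list("ABCDEFG")
        x = pd.Series(rng.normal(size=7), index=labels)
        y = pd.Series(rng.normal(size=7), index=labels)
        fit = pp.pgls(star, y, x)
        ols = stats.linregress(x.to_numpy(), y.to_numpy())
        assert fit.slope == pytest.approx(ols.slope, abs=1e-9)
        assert fit.intercept == pytest.approx(ols.intercept, abs=1e-9)
        assert fit.slope_p == pytest.approx(ols.pvalue, abs=1e-9)

    def test_identity_response(self, tree32):
        x = pp.simulate_bm(tree32, seed=21).iloc[:, 0]
        fit = pp.pgls(tree32, x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.pseudo_r2_adj == pytest.approx(1.0, abs=1e-9)

    def test_slope_recovery_under_bm(self):
        tree = synth.pure_birth_tree(64, seed=3)
        slopes = []
        for i in range(200):
            x = pp.simulate_bm(tree, rate=1.0, seed=1000 + i).iloc[:, 0]
            err = pp.simulate_bm(tree, rate=0.25, seed=5000 + i).iloc[:, 0]
            slopes.append(pp.pgls(tree, 0.5 * x + err, x).slope)
        assert 0.45 <= np.mean(slopes) <= 0.55

    def test_identity_covariance_estimator_equals_ols(self, rng):
        x = rng.normal(size=12)
        y = 1.5 * x + rng.normal(size=12)
        est = pp.PGLSRegression(covariance=np.eye(12)).fit(x, y)
        ols = stats.linregress(x, y)
        assert est.coef_[0] == pytest.approx(ols.slope, abs=1e-12)
        assert est.slope_pvalues_[0] == pytest.approx(ols.pvalue, abs=1e-12)

    def test_too_few_tips(self):
        t = pp.tree_from_string("(A:1,B:1,C:1);")
        s = pd.Series([1.0, 2.0, 3.0], index=list("ABC"))
        with pytest.raises(ValueError, match="at least 4"):
            pp.pgls(t, s, s * 2)


class TestSimulateBM:
    def test_rate_zero_limit_collapses_to_root_state(self, tree32):
        tr = pp.simulate_bm(tree32, rate=1e-30, seed=1, root_state=2.5)
        np.testing.assert_allclose(tr.to_numpy(), 2.5, atol=1e-10)

    def test_fixed_seed_reproducible(self, tree32):
        a = pp.simulate_bm(tree32, n_traits=3, seed=77)
        b = pp.simulate_bm(tree32, n_traits=3, seed=77)
        pd.testing.assert_frame_equal(a, b)

    def test_monte_carlo_tip_covariance(self):
        tree = synth.pure_birth_tree(6, seed=8)
        c = pp.bm_covariance(tree).to_numpy()
        rate = 2.0
        draws = np.stack([pp.simulate_bm(tree, rate=rate, seed=i).iloc[:, 0]
                          for i in range(2000)])
        emp = np.cov(draws.T)
        scale = np.abs(rate * c).max()
        np.testing.assert_allclose(emp, rate * c, atol=0.1 * scale)
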