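"""Procrustes superimposition, shape PCA, outlier tests, allometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from craniomech import morphometrics as mm
from craniomech import synthetic_data as synth

from conftest import rotation


class TestCentroidSize:
    def test_unit_square(self):
        pts = np.array([[0.5, 0.5], [-0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        assert mm.centroid_size(pts) == pytest.approx(np.sqrt(2), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(k=st.floats(0.01, 100.0))
    def test_homogeneity_under_scaling(self, k):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 2))
        assert mm.centroid_size(k * pts) == pytest.approx(
            k * mm.centroid_size(pts), rel=1e-12)

    def test_matches_brute_force_summation(self, rng):
        pts = rng.normal(size=(10, 2))
        centroid = pts.mean(axis=0)
        brute = np.sqrt(sum((p - centroid) @ (p - centroid) for p in pts))
        assert mm.centroid_size(pts) == pytest.approx(brute, rel=1e-14)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            mm.centroid_size(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            mm.centroid_size(np.array([[1.0, 2.0]]))


class TestGPA:
    def test_exact_superimposability(self, rng):
        base = rng.normal(size=(12, 2))
        copy = 2.0 * base @ rotation(np.pi / 2).T + np.array([5.0, -3.0])
        res = mm.gpa(np.stack([base, copy]))
        d = mm.procrustes_distance(res.aligned_points[0], res.aligned_points[1])
        assert d == pytest.approx(0.0, abs=1e-9)
        res.validate()

    def test_invariance_to_per_specimen_similarity(self, rng):
        base = rng.normal(size=(8, 2))
        shapes = base[None] + 0.2 * rng.normal(size=(5, 8, 2))
        moved = np.stack([
            s * rng.uniform(0.5, 3.0) @ rotation(rng.uniform(0, 2 * np.pi)).T
            + rng.normal(size=2) * 10
            for s in shapes])
        a = mm.gpa(shapes)
        b = mm.gpa(moved)
        np.testing.assert_allclose(a.aligned_points, b.aligned_points, atol=1e-7)
        # pairwise Procrustes distances agree too
        for i in range(5):
            for j in range(i + 1, 5):
                da = mm.procrustes_distance(a.aligned_points[i], a.aligned_points[j])
                db = mm.procrustes_distance(b.aligned_points[i], b.aligned_points[j])
                assert da == pytest.approx(db, abs=1e-9)

    def test_rotation_matches_grid_search_oracle(self, rng):
        """Optimal rotation for two 3-point shapes vs exhaustive search."""
        a = rng.normal(size=(3, 2))
        b = rng.normal(size=(3, 2))
        a = (a - a.mean(0)) / mm.centroid_size(a)
        b = (b - b.mean(0)) / mm.centroid_size(b)
        thetas = np.arange(0, 2 * np.pi, 0.001)
        ssd = [((a @ rotation(t).T - b) ** 2).sum() for t in thetas]
        best = min(ssd)
        r = mm._optimal_rotation(a, b)
        achieved = ((a @ r - b) ** 2).sum()
        assert achieved <= best + 1e-6
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_consensus_is_mean_and_sizes_returned(self, rng):
        shapes = rng.normal(size=(4, 6, 2)) * 3
        res = mm.gpa(shapes)
        np.testing.assert_allclose(res.consensus,
                                   res.aligned_points.mean(axis=0), atol=1e-12)
        for s, orig in zip(res.centroid_sizes, shapes):
            assert s == pytest.approx(mm.centroid_size(orig))

    def test_too_few_configurations(self, rng):
        with pytest.raises(ValueError):
            mm.gpa(rng.normal(size=(1, 5, 2)))


class TestShapePCA:
    def test_identical_specimens_have_zero_variance(self, rng):
        shape = rng.normal(size=(6, 2))
        aligned = mm.gpa(np.stack([shape] * 4))
        res = mm.pca_shapes(aligned)
        np.testing.assert_allclose(res.variance_fraction, 0.0, atol=1e-12)

    def test_two_distinct_shapes_duplicated_give_one_component(self, rng):
        a = rng.normal(size=(7, 2))
        b = a + rng.normal(size=(7, 2)) * 0.1
        aligned = mm.gpa(np.stack([a, a, b, b]))
        res = mm.pca_shapes(aligned)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)
        assert res.variance_fraction[1:].max() < 1e-9

    def test_variance_fractions_sum_to_one(self, rng):
        aligned = mm.gpa(rng.normal(size=(8, 10, 2)))
        res = mm.pca_shapes(aligned)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        # loadings orthonormal
        g = res.loadings @ res.loadings.T
        np.testing.assert_allclose(g, np.eye(len(g)), atol=1e-9)

    def test_total_variance_equals_mean_squared_distance_to_consensus(self, rng):
        aligned = mm.gpa(rng.normal(size=(6, 9, 2)))
        res = mm.pca_shapes(aligned)
        flat = aligned.aligned_points.reshape(6, -1)
        centred = flat - flat.mean(axis=0)
        total = (centred ** 2).sum() / (6 - 1)
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-9)

    def test_single_mode_recovery(self):
        """PC1 recovers a single generating deformation mode."""
        rng = np.random.default_rng(3)
        base = rng.normal(size=(10, 2))
        mode = rng.normal(size=(10, 2))
        mode -= mode.mean(axis=0)
        weights = np.linspace(-1, 1, 8)
        shapes = np.stack([base + w * mode * 0.1
                           + rng.normal(size=(10, 2)) * 1e-4 for w in weights])
        res = mm.pca_shapes(mm.gpa(shapes))
        assert res.variance_fraction[0] > 0.95
        r = np.corrcoef(res.scores[:, 0], weights)[0, 1]
        assert abs(r) > 0.99
        # scores monotone in the generating weight
        order = np.argsort(res.scores[:, 0] * np.sign(r))
        assert np.array_equal(order, np.arange(8))

    def test_sign_convention_deterministic(self, rng):
        shapes = rng.normal(size=(5, 6, 2))
        r1 = mm.pca_shapes(mm.gpa(shapes))
        r2 = mm.pca_shapes(mm.gpa(shapes))
        np.testing.assert_array_equal(r1.scores, r2.scores)
        for row in r1.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_requires_three_specimens(self, rng):
        with pytest.raises(ValueError):
            mm.pca_shapes(mm.gpa(rng.normal(size=(2, 5, 2))))

    def test_k_orthogonal_modes_give_k_eigenvalues(self):
        rng = np.random.default_rng(9)
        k_modes = 3
        base = rng.normal(size=(12, 2))
        flat_modes = np.linalg.qr(rng.normal(size=(24, k_modes)))[0].T
        shapes = []
        for i in range(10):
            w = rng.normal(size=k_modes) * 0.01
            shapes.append(base + (w @ flat_modes).reshape(12, 2))
        res = mm.pca_shapes(np.stack(shapes))  # PCA directly on coordinates
        total = res.eigenvalues.sum()
        assert np.sum(res.eigenvalues / total > 1e-8) == k_modes


class TestBoxplotOutliers:
    def test_brute_force_example(self):
        rep = mm.boxplot_outliers({"a": 1, "b": 2, "c": 3, "d": 4, "e": 100})
        vals = np.sort([1, 2, 3, 4, 100])
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        assert rep.lower_fence == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert rep.upper_fence == pytest.approx(q3 + 1.5 * (q3 - q1))
        assert rep.outliers == [("e", 100.0, "upper")]

    def test_constant_vector_has_no_outliers(self):
        assert mm.boxplot_outliers([5.0] * 6).outliers == []

    def test_negation_swaps_sides(self, rng):
        vals = np.concatenate([rng.normal(size=20), [15.0, -12.0]])
        up = {s for s, _, side in mm.boxplot_outliers(vals).outliers
              if side == "upper"}
        down = {s for s, _, side in mm.boxplot_outliers(-vals).outliers
                if side == "lower"}
        assert up == down

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            vals = rng.normal(size=rng.integers(4, 30))
            rep = mm.boxplot_outliers(vals)
            srt = np.sort(vals)
            # type-7 quartiles by manual interpolation
            def q(p):
                h = (len(srt) - 1) * p
                lo = int(np.floor(h))
                return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])
            iqr = q(0.75) - q(0.25)
            expect = {(str(i), v) for i, v in enumerate(vals)
                      if v < q(0.25) - 1.5 * iqr or v > q(0.75) + 1.5 * iqr}
            got = {(s, v) for s, v, _ in rep.outliers}
            assert got == expect

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            mm.boxplot_outliers([1.0, 2.0, 3.0])


class TestAllometryRegression:
    def test_exact_line(self):
        x = np.arange(1.0, 6.0)
        fit = mm.regress_allometry(2 * x, x)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_response(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])  # symmetric in x
        assert mm.regress_allometry(y, x).slope == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = mm.regress_allometry(y, x)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
        assert fit.slope == pytest.approx(beta[1], rel=1e-9)

    def test_zero_variance_predictor(self):
        with pytest.raises(ValueError):
            mm.regress_allometry([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
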