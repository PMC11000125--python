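"""Manifold analysis tests with independent oracles for PCA and ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bciadapt import manifold as mf


def _random_activity(rng, n_units=10, n_obs=500):
    values = rng.standard_normal((n_units, n_obs)) * rng.uniform(0.5, 2.0, (n_units, 1))
    return mf.ActivityMatrix(
        values=values,
        target_id=rng.integers(0, 8, n_obs),
        condition=np.full(n_obs, "x", dtype=object),
    )


class TestPCA:
    def test_matches_covariance_eigendecomposition(self):
        # oracle: eigenvectors of the biased sample covariance
        rng = np.random.default_rng(0)
        mat = _random_activity(rng)
        basis = mf.fit_pca(mat, n_components=2)
        centered = mat.values - mat.values.mean(axis=1, keepdims=True)
        cov = centered @ centered.T / centered.shape[1]
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        for i in range(2):
            v = evecs[:, order[i]]
            dot = abs(v @ basis.components[i])
            assert dot == pytest.approx(1.0, abs=1e-8)
            # singular value^2 / n_obs equals the eigenvalue
            assert basis.singular_values[i] ** 2 / centered.shape[1] == pytest.approx(
                evals[order[i]], rel=1e-8
            )

    def test_collinear_data_gives_zero_second_singular_value(self):
        direction = np.array([1.0, 2.0, -1.0])
        t = np.linspace(-1, 1, 50)
        values = np.outer(direction, t) + 5.0
        mat = mf.ActivityMatrix(values, np.zeros(50, int), np.full(50, "c", object))
        basis = mf.fit_pca(mat)
        assert abs(abs(basis.components[0] @ (direction / np.linalg.norm(direction)))) == pytest.approx(1.0, abs=1e-10)
        assert basis.singular_values[1] == pytest.approx(0.0, abs=1e-10)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        mat = _random_activity(rng, n_units=6, n_obs=40)
        basis = mf.fit_pca(mat, n_components=6)
        centered = mat.values - basis.mean[:, None]
        scores = mf.project(basis, mat)
        np.testing.assert_allclose(
            basis.components.T @ scores, centered, atol=1e-10
        )

    def test_constant_matrix_rejected(self):
        mat = mf.ActivityMatrix(
            np.full((4, 30), 2.0), np.zeros(30, int), np.full(30, "c", object)
        )
        with pytest.raises(ValueError, match="constant"):
            mf.fit_pca(mat)

    def test_projection_of_mean_is_zero(self):
        rng = np.random.default_rng(2)
        mat = _random_activity(rng)
        basis = mf.fit_pca(mat)
        mean_mat = mf.ActivityMatrix(
            basis.mean[:, None], np.zeros(1, int), np.full(1, "c", object)
        )
        np.testing.assert_allclose(mf.project(basis, mean_mat), 0.0, atol=1e-10)

    def test_score_covariance_diagonal_on_fit_data(self):
        rng = np.random.default_rng(3)
        mat = _random_activity(rng)
        basis = mf.fit_pca(mat, n_components=3)
        scores = mf.project(basis, mat)
        cov = np.cov(scores)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * cov.max()

    def test_shared_basis_projection_allowed(self):
        rng = np.random.default_rng(4)
        basis = mf.fit_pca(_random_activity(rng))
        other = _random_activity(rng)
        assert mf.project(basis, other).shape == (2, other.values.shape[1])


class TestCentroids:
    def test_single_cluster_angle(self):
        scores = np.array([[1.0, 1.0], [1.0, 1.0]])
        cents = mf.target_centroids(scores, np.array([0, 0]))
        assert cents.angles_deg[0] == pytest.approx(45.0)

    def test_point_reflection_symmetry(self):
        scores = np.array([[1.0, 1.0, -1.0, -1.0], [0.5, 0.5, -0.5, -0.5]])
        cents = mf.target_centroids(scores, np.array([0, 0, 1, 1]))
        diff = mf.circular_difference_deg(cents.angles_deg[1], cents.angles_deg[0])
        assert abs(diff) == pytest.approx(180.0)

    def test_missing_target_rejected(self):
        scores = np.ones((2, 4))
        with pytest.raises(ValueError, match="1"):
            mf.target_centroids(scores, np.zeros(4, int), expected_targets=[0, 1])

    def test_octagon_gaps_all_45(self):
        ang = np.deg2rad(np.arange(8) * 45.0 + 13.0)
        scores = np.stack([np.cos(ang), np.sin(ang)]).repeat(2, axis=1)
        cents = mf.target_centroids(scores, np.repeat(np.arange(8), 2))
        np.testing.assert_allclose(mf.adjacent_centroid_angles(cents), 45.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-179.0, 180.0), min_size=3, max_size=12, unique=True))
    def test_gaps_sum_to_360(self, angles):
        cents = mf.CentroidSet(
            target_ids=np.arange(len(angles)),
            centroids=np.stack(
                [np.cos(np.deg2rad(angles)), np.sin(np.deg2rad(angles))], axis=1
            ),
        )
        assert mf.adjacent_centroid_angles(cents).sum() == pytest.approx(360.0)


class TestDisplacement:
    def _octagon(self, offset_deg=0.0):
        ang = np.deg2rad(np.arange(8) * 45.0 + offset_deg)
        return mf.CentroidSet(
            target_ids=np.arange(8),
            centroids=np.stack([np.cos(ang), np.sin(ang)], axis=1),
        )

    def test_identical_sets_zero_displacement(self):
        res = mf.centroid_angular_displacement(self._octagon(), self._octagon())
        np.testing.assert_allclose(res.per_target_deg, 0.0, atol=1e-12)
        assert res.mean_deg == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_recovered(self):
        res = mf.centroid_angular_displacement(self._octagon(), self._octagon(-50.0))
        assert res.mean_deg == pytest.approx(-50.0)
        assert res.sd_deg == pytest.approx(0.0, abs=1e-9)

    def test_wraparound_convention(self):
        before = mf.CentroidSet(
            target_ids=np.array([0]),
            centroids=np.array([[np.cos(np.deg2rad(179)), np.sin(np.deg2rad(179))]]),
        )
        after = mf.CentroidSet(
            target_ids=np.array([0]),
            centroids=np.array([[np.cos(np.deg2rad(-179)), np.sin(np.deg2rad(-179))]]),
        )
        res = mf.centroid_angular_displacement(before, after)
        assert res.per_target_deg[0] == pytest.approx(2.0)

    def test_roster_mismatch_rejected(self):
        other = mf.CentroidSet(
            target_ids=np.arange(1, 9), centroids=self._octagon().centroids
        )
        with pytest.raises(ValueError, match="roster"):
            mf.centroid_angular_displacement(self._octagon(), other)


class TestRegression:
    def test_exact_compensation_line(self):
        thetas = np.array([50.0, -50.0, 90.0, -90.0, 110.0, -110.0])
        reg = mf.regress_displacement(-thetas, thetas)
        assert reg.slope == pytest.approx(-1.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_zero_displacements_zero_slope(self):
        thetas = np.array([50.0, 90.0, 110.0])
        reg = mf.regress_displacement(np.zeros(3), thetas)
        assert reg.slope == pytest.approx(0.0)

    def test_too_few_thetas_rejected(self):
        with pytest.raises(ValueError):
            mf.regress_displacement(np.array([1.0, 2.0]), np.array([50.0, 90.0]))


class TestNormalizedDifference:
    def test_toy_substitution(self):
        d = mf.normalized_difference(np.array([10.0, 20.0, 30.0]), np.zeros(3))
        np.testing.assert_allclose(d, [0.5, 1.0, 1.5])

    def test_identical_gives_zero(self):
        b = np.array([3.0, 4.0, 5.0])
        np.testing.assert_allclose(mf.normalized_difference(b, b), 0.0)

    def test_scale_invariance(self):
        b = np.array([10.0, 20.0, 30.0])
        r = np.array([5.0, 15.0, 40.0])
        np.testing.assert_allclose(
            mf.normalized_difference(b, r), mf.normalized_difference(2 * b, 2 * r)
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        b = rng.uniform(1.0, 10.0, 12)
        r = rng.uniform(1.0, 10.0, 12)
        d1 = mf.normalized_difference(b, r)
        d2 = mf.normalized_difference(r, b)
        # swapping negates each d_i up to the (different) normalizing mean
        np.testing.assert_allclose(d1 * b.mean(), -d2 * r.mean(), rtol=1e-10)

    def test_zero_baseline_mean_rejected(self):
        with pytest.raises(ValueError):
            mf.normalized_difference(np.zeros(3), np.ones(3))


class TestCosineSimilarity:
    def test_parallel_antiparallel_orthogonal(self):
        v = np.array([1.0, 2.0, 3.0])
        assert mf.abs_cosine_similarity(v, v) == pytest.approx(1.0)
        assert mf.abs_cosine_similarity(v, -v) == pytest.approx(1.0)
        assert mf.abs_cosine_similarity(
            np.array([1.0, 0.0]), np.array([0.0, 5.0])
        ) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        assert 0.0 <= mf.abs_cosine_similarity(a, b) <= 1.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            mf.abs_cosine_similarity(np.zeros(3), np.ones(3))

    def test_scaling_cannot_change_cosine(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        assert mf.abs_cosine_similarity(3.7 * a, b) == pytest.approx(
            mf.abs_cosine_similarity(a, b)
        )


class TestPreservationReport:
    def test_identical_data_full_similarity(self):
        rng = np.random.default_rng(6)
        mat = _random_activity(rng, n_units=8, n_obs=200)
        mat.values += 5.0  # nonzero mean activity
        stats = mf.manifold_preservation_report([mat], [mat])[0]
        assert stats.mean_similarity == pytest.approx(1.0)
        assert stats.pc1_similarity == pytest.approx(1.0)
        assert stats.pc2_similarity == pytest.approx(1.0)
        np.testing.assert_allclose(stats.mean_normdiff, 0.0, atol=1e-12)
        np.testing.assert_allclose(stats.pc1_normdiff, 0.0, atol=1e-9)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            mf.manifold_preservation_report([], [], mode="bogus")


def _anova_oracle(groups):
    """Hand-coded one-way ANOVA sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    from scipy.stats import f as fdist

    return f, float(fdist.sf(f, df_b, df_w))


class TestGroupComparison:
    def test_matches_hand_coded_anova(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.0, n) for m, n in [(0, 10), (0.5, 14), (1.2, 8)]]
        f, p = mf.compare_group_means(*groups)
        f0, p0 = _anova_oracle(groups)
        assert f == pytest.approx(f0, rel=1e-10)
        assert p == pytest.approx(p0, rel=1e-10)

    def test_identical_groups_f_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        f, p = mf.compare_group_means(g, g.copy())
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_effect_significant(self):
        rng = np.random.default_rng(8)
        f, p = mf.compare_group_means(
            rng.normal(0, 1, 50), rng.normal(10, 1, 50)
        )
        assert p < 1e-3

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            mf.compare_group_means(np.array([1.0]), np.array([1.0, 2.0]))
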