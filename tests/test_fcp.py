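"""Fuzzy clustering with fixed prototypes: distances, memberships, detection."""

import numpy as np
import pytest

from aliseg import (
    BinarizeParams,
    CohortStack,
    FCPParams,
    ProbVolume,
    binarize,
    build_centroids,
    combine_max,
    detect_tissue_outliers,
    fcp_distance,
    fcp_membership,
)
from aliseg.fcp import FuzzyLesionMap, _distance_matrix


def loo_distance(p, j, alpha):
    """Leave-one-out oracle: D = 1 - tanh(n*(mean incl j - mean excl j)/alpha)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    incl = p.mean()
    excl = (p.sum() - p[j]) / (n - 1)
    return 1.0 - np.tanh(n * (incl - excl) / alpha)


class TestCentroids:
    def test_diagonal_alpha(self):
        v = build_centroids(3, -0.5)
        assert np.array_equal(v, np.diag([-0.5, -0.5, -0.5]))

    def test_alpha_one_is_identity(self):
        assert np.array_equal(build_centroids(5, 1.0), np.eye(5))

    def test_zero_alpha_rejected(self):
        with pytest.raises(ValueError):
            build_centroids(5, 0.0)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_centroids(2, -0.5)


class TestDistance:
    def test_constant_vector_gives_unit_distance(self):
        v = build_centroids(6, -0.5)
        for j in range(6):
            assert fcp_distance(np.full(6, 0.4), j, v, -0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("n_sub", [3, 10, 64])
    def test_covariance_form_equals_leave_one_out_form(self, n_sub, rng):
        """The two printed forms of D coincide exactly (sample covariance)."""
        alpha = -0.5
        v = build_centroids(n_sub, alpha)
        for _ in range(1000 // n_sub + 5):
            p = rng.uniform(size=n_sub)
            for j in range(n_sub):
                d_cov = fcp_distance(p, j, v, alpha)
                assert d_cov == pytest.approx(loo_distance(p, j, alpha), abs=1e-10)

    def test_distance_strictly_inside_zero_two(self, rng):
        alpha = -0.5
        v = build_centroids(10, alpha)
        for _ in range(200):
            p = rng.uniform(size=10)
            j = rng.integers(10)
            d = fcp_distance(p, j, v, alpha)
            assert 0.0 < d < 2.0

    def test_vectorized_matrix_matches_scalar(self, rng):
        alpha = -0.5
        n = 8
        v = build_centroids(n, alpha)
        pmat = rng.uniform(size=(n, 40))
        dmat = _distance_matrix(pmat, alpha)
        for i in (0, 13, 39):
            for j in range(n):
                assert dmat[j, i] == pytest.approx(
                    fcp_distance(pmat[:, i], j, v, alpha), abs=1e-12
                )


class TestMembership:
    def test_equal_distances_give_uniform_membership(self):
        u = fcp_membership(np.full(8, 0.7), lam=-4.0)
        assert np.allclose(u, 1.0 / 8.0, atol=1e-12)

    def test_lambda_to_zero_is_fuzzy(self, rng):
        d = rng.uniform(0.5, 1.5, size=12)
        u = fcp_membership(d, lam=-1e-6)
        assert np.abs(u - 1.0 / 12.0).max() < 1e-4

    def test_very_negative_lambda_is_crisp(self):
        d = np.array([0.4, 1.0, 1.1, 0.9])
        u = fcp_membership(d, lam=-100.0)
        assert u[0] > 0.999

    def test_direct_formula_oracle(self):
        d = np.array([0.5, 1.0, 2.0])
        u = fcp_membership(d, lam=-4.0)
        total = 16.0 + 1.0 + 1.0 / 16.0
        assert u == pytest.approx([16.0 / total, 1.0 / total, (1.0 / 16.0) / total])

    def test_memberships_sum_to_one(self, rng):
        for _ in range(50):
            d = rng.uniform(0.01, 1.99, size=rng.integers(3, 30))
            u = fcp_membership(d, lam=-4.0)
            assert abs(u.sum() - 1.0) < 1e-12
            assert u.min() >= 0.0 and u.max() <= 1.0


def _stack_from_matrix(mat, shape=(4, 4, 4), patient_index=None):
    """Build a CohortStack whose masked voxels carry the given columns."""
    n_sub, n_vox = mat.shape
    maps = []
    for i in range(n_sub):
        data = np.zeros(shape)
        data.reshape(-1)[:n_vox] = mat[i]
        maps.append(ProbVolume(data))
    mask = np.zeros(shape, dtype=bool)
    mask.reshape(-1)[:n_vox] = True
    if patient_index is None:
        patient_index = n_sub - 1
    return CohortStack(maps=maps, patient_index=patient_index, analysis_mask=mask)


class TestDetect:
    def test_patient_at_control_mean_is_unremarkable(self, rng):
        n = 13
        base = rng.uniform(0.3, 0.9, size=50)
        mat = base + rng.normal(0, 0.01, size=(n, 50))
        mat[-1] = mat[:-1].mean(axis=0)  # patient equals the control mean
        stack = _stack_from_matrix(np.clip(mat, 0, 1), shape=(5, 5, 5))
        fuzzy = detect_tissue_outliers(stack, FCPParams())
        u = fuzzy.u.data[stack.analysis_mask]
        assert u.max() < 2.0 / n

    def test_zeroed_sphere_is_flagged(self, priors, cohort):
        """Planted outlier: the patient's GM zeroed in a 10 mm sphere."""
        controls = cohort.gm
        grid = controls[0]
        center = (np.asarray(grid.shape) - 1) / 2.0
        axes = [
            (np.arange(n) - c) * s
            for n, c, s in zip(grid.shape, center, grid.spacing)
        ]
        coords = np.meshgrid(*axes, indexing="ij")
        # sphere planted in the GM shell, where controls carry GM signal
        sphere = (coords[0] ** 2 + (coords[1] - 34.0) ** 2
                  + coords[2] ** 2) <= 10.0**2
        patient = ProbVolume(
            np.where(sphere, 0.0, np.mean([m.data for m in controls], axis=0)),
            grid.spacing, grid.origin,
        )
        stack = CohortStack(maps=list(controls) + [patient],
                            patient_index=len(controls))
        fuzzy = detect_tissue_outliers(stack, FCPParams())
        u = fuzzy.u.data
        inside = u[sphere & stack.analysis_mask].mean()
        outside = u[~sphere & stack.analysis_mask].mean()
        assert inside > 0.5
        assert inside > 5 * outside

    def test_u_values_within_unit_interval(self, rng):
        mat = rng.uniform(size=(6, 30))
        fuzzy = detect_tissue_outliers(_stack_from_matrix(mat), FCPParams())
        assert fuzzy.u.data.min() >= 0.0 and fuzzy.u.data.max() <= 1.0

    def test_low_outliers_targeted_with_negative_alpha(self):
        """A value below the control mean scores higher U than its mirror above."""
        n = 10
        mat = np.full((n, 2), 0.6)
        mat[-1, 0] = 0.3   # patient low at voxel 0
        mat[-1, 1] = 0.9   # patient high at voxel 1
        fuzzy = detect_tissue_outliers(_stack_from_matrix(mat), FCPParams(alpha=-0.5))
        u = fuzzy.u.data.reshape(-1)[:2]
        assert u[0] > u[1]

    def test_permuting_controls_leaves_patient_u_unchanged(self, rng):
        mat = rng.uniform(size=(8, 25))
        base = detect_tissue_outliers(_stack_from_matrix(mat), FCPParams())
        perm = rng.permutation(7)
        mat2 = np.vstack([mat[:7][perm], mat[7:]])
        shuffled = detect_tissue_outliers(_stack_from_matrix(mat2), FCPParams())
        assert np.abs(base.u.data - shuffled.u.data).max() < 1e-12

    def test_duplicated_control_keeps_null_u_in_band(self, rng):
        mat = rng.uniform(0.4, 0.6, size=(10, 30))
        mat = np.vstack([mat, mat[:1]])  # duplicate one control
        n = mat.shape[0]
        fuzzy = detect_tissue_outliers(_stack_from_matrix(mat), FCPParams())
        u = fuzzy.u.data[_stack_from_matrix(mat).analysis_mask]
        assert np.all(u >= 0)
        assert u.max() < 2.0 / n * 3  # null stays near 1/N

    def test_small_cohort_rejected(self, rng):
        with pytest.raises(ValueError):
            _stack_from_matrix(rng.uniform(size=(2, 10)))


class TestCombineAndBinarize:
    def _fuzzy(self, data):
        mask = np.ones(data.shape, dtype=bool)
        return FuzzyLesionMap(ProbVolume(data), mask)

    def test_combine_max_idempotent_commutative(self, rng):
        a = self._fuzzy(rng.uniform(size=(5, 5, 5)))
        b = self._fuzzy(rng.uniform(size=(5, 5, 5)))
        assert np.array_equal(combine_max(a, a).u.data, a.u.data)
        assert np.array_equal(
            combine_max(a, b).u.data, combine_max(b, a).u.data
        )

    def test_zero_is_identity_element(self, rng):
        a = self._fuzzy(rng.uniform(size=(5, 5, 5)))
        z = self._fuzzy(np.zeros((5, 5, 5)))
        assert np.array_equal(combine_max(a, z).u.data, a.u.data)

    def test_threshold_at_0p3(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = 0.2
        data[1, 1, 1] = 0.4
        mask = binarize(self._fuzzy(data), BinarizeParams(u_threshold=0.3))
        assert mask[1, 1, 1] and not mask[0, 0, 0]
        assert mask.sum() == 1

    def test_threshold_nesting(self, rng):
        f = self._fuzzy(rng.uniform(size=(6, 6, 6)))
        m_low = binarize(f, BinarizeParams(u_threshold=0.2))
        m_high = binarize(f, BinarizeParams(u_threshold=0.6))
        assert np.all(m_low[m_high])  # mask(t2) subset of mask(t1)

    def test_cluster_extent_filter(self):
        data = np.zeros((12, 12, 12))
        data[1, 1, 1:6] = 0.9          # 5-voxel line
        data[6:8, 6:11, 6:11] = 0.9    # 50-voxel block
        f = self._fuzzy(data)
        mask = binarize(f, BinarizeParams(u_threshold=0.5, min_cluster_voxels=10))
        assert not mask[1, 1, 1]
        assert mask[6, 6, 6]
        assert mask.sum() == 50

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            BinarizeParams(u_threshold=1.5)


def test_fcp_parameter_validation():
    with pytest.raises(ValueError):
        FCPParams(alpha=0.0)
    with pytest.raises(ValueError):
        FCPParams(lam=1.0)
    with pytest.raises(ValueError):
        FCPParams(d_epsilon=1e-6)
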