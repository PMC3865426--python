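"""Fuzzy Clustering with fixed Prototypes (FCP) outlier detection.

The patient's smoothed GM (or WM) probability map is compared voxelwise
against a cohort of controls.  Each of the ``N_sub`` subjects (controls
plus the patient) defines one fixed cluster prototype: the centroid of
cluster ``j`` is a vector of zeros except entry ``j``, set to the tuning
constant ``alpha``.  At each voxel the distance of the subject vector
``P_i`` to centroid ``j`` is

    ``D_ij = 1 - tanh( (N_sub / alpha^2) * cov(P_i, V_j) )``

with ``cov`` the sample covariance (divisor ``N_sub - 1``); this is
algebraically identical to the leave-one-out form

    ``D_ij = 1 - tanh( N_sub * (mean incl. j - mean excl. j) / alpha )``

so ``D_ij`` measures how much subject ``j`` perturbs the group mean.
Distances are defuzzified into memberships

    ``U_ij = D_ij^lambda / sum_j' D_ij'^lambda``   (``lambda < 0``)

and the patient-cluster membership ``U`` is the per-voxel degree of
abnormality.  With ``alpha < 0`` (default -0.5) the detector flags
abnormally LOW tissue probability — missing grey or white matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .core_io import ProbVolume, Volume3D, check_same_grid

#: default minimum control-mean tissue probability defining the analysis mask
DEFAULT_MASK_THRESHOLD = 0.01


@dataclass
class FCPParams:
    """Tuning constants of the fuzzy outlier detector.

    ``alpha``: sensitivity and direction of outlier detection; negative
    targets abnormally low tissue probability.  Default -0.5.
    ``lam``: defuzzification exponent; more negative makes memberships
    crisper.  Default -4.
    ``d_epsilon``: numerical floor applied to distances before raising
    to the negative power ``lam``.
    """

    alpha: float = -0.5
    lam: float = -4.0
    d_epsilon: float = 1e-12

    def __post_init__(self):
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero (it sets the method's scale)")
        if self.lam >= 0:
            raise ValueError("lam must be negative")
        if not (0 < self.d_epsilon <= 1e-8):
            raise ValueError("d_epsilon must be in (0, 1e-8]")


@dataclass
class CohortStack:
    """Aligned probability maps of one tissue class for all subjects."""

    maps: list[ProbVolume]
    patient_index: int
    analysis_mask: np.ndarray | None = None

    def __post_init__(self):
        if len(self.maps) < 3:
            raise ValueError(f"FCP needs at least 3 subjects, got {len(self.maps)}")
        if not (0 <= self.patient_index < len(self.maps)):
            raise ValueError("patient_index out of range")
        check_same_grid(self.maps)
        if self.analysis_mask is None:
            # voxels where controls carry appreciable tissue probability;
            # elsewhere P_i ~ 0 for everyone and U is uninformative noise
            controls = [
                m.data for k, m in enumerate(self.maps) if k != self.patient_index
            ]
            self.analysis_mask = np.mean(controls, axis=0) > DEFAULT_MASK_THRESHOLD
        self.analysis_mask = np.asarray(self.analysis_mask, dtype=bool)
        if self.analysis_mask.shape != self.maps[0].shape:
            raise ValueError("analysis_mask grid mismatch")

    @property
    def n_sub(self) -> int:
        return len(self.maps)

    def as_array(self) -> np.ndarray:
        """(n_sub, n_mask_voxels) matrix of tissue probabilities."""
        return np.stack([m.data[self.analysis_mask] for m in self.maps])


@dataclass
class FuzzyLesionMap:
    """Per-voxel degree of abnormality U in [0, 1], zero outside the mask."""

    u: ProbVolume
    mask: np.ndarray
    tissue: str = "combined"

    def __post_init__(self):
        if self.u.data.min() < 0 or self.u.data.max() > 1:
            raise ValueError("U values must lie in [0, 1]")


@dataclass
class BinarizeParams:
    """U threshold and optional cluster-extent filter for the binary lesion."""

    u_threshold: float = 0.3
    min_cluster_voxels: int = 0
    connectivity: int = 26

    def __post_init__(self):
        if not (0 < self.u_threshold < 1):
            raise ValueError("u_threshold must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def build_centroids(n_sub: int, alpha: float) -> np.ndarray:
    """The fixed prototypes: ``V[k, j] = alpha`` if ``k == j`` else 0."""
    if n_sub < 3:
        raise ValueError("n_sub must be >= 3")
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    return alpha * np.eye(n_sub)


def fcp_distance(p: np.ndarray, j: int, centroids: np.ndarray, alpha: float) -> float:
    """Distance of one voxel's subject vector to cluster ``j``.

    Uses the covariance form with the sample covariance (divisor
    ``n_sub - 1``), the unique divisor under which the covariance and
    leave-one-out forms coincide.  The result lies strictly in (0, 2).
    """
    p = np.asarray(p, dtype=float)
    n_sub = centroids.shape[0]
    if p.shape != (n_sub,):
        raise ValueError(f"subject vector length {p.shape} != n_sub {n_sub}")
    v = centroids[:, j]
    cov = float(np.cov(p, v, ddof=1)[0, 1])
    return 1.0 - np.tanh(n_sub / alpha**2 * cov)


def fcp_membership(d: np.ndarray, lam: float, d_epsilon: float = 1e-12) -> np.ndarray:
    """Defuzzified memberships ``U_j = d_j^lam / sum d^lam`` over clusters."""
    d = np.maximum(np.asarray(d, dtype=float), d_epsilon)
    if np.any(d <= 0):
        raise FloatingPointError("nonpositive distance after flooring")
    # compute in log space: with lam very negative d**lam overflows
    logw = lam * np.log(d)
    logw -= logw.max(axis=0 if d.ndim > 1 else None)
    w = np.exp(logw)
    return w / w.sum(axis=0 if d.ndim > 1 else None)


def _distance_matrix(p_mat: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized D over all clusters: (n_sub, n_voxels).

    ``(n/alpha^2) * cov(P, V_j) = n * (P_j - mean(P)) / (alpha * (n-1))``.
    """
    n = p_mat.shape[0]
    centred = p_mat - p_mat.mean(axis=0, keepdims=True)
    return 1.0 - np.tanh(n * centred / (alpha * (n - 1)))


def detect_tissue_outliers(
    stack: CohortStack, params: FCPParams | None = None, tissue: str = "combined"
) -> FuzzyLesionMap:
    """Patient-cluster membership U at every voxel of the analysis mask.

    The input maps must already be smoothed (the driver smooths at 8 mm
    FWHM); voxels outside the analysis mask get U = 0.
    """
    params = params or FCPParams()
    p_mat = stack.as_array()
    d = _distance_matrix(p_mat, params.alpha)
    u_all = fcp_membership(d, params.lam, params.d_epsilon)
    grid = stack.maps[0]
    u = np.zeros(grid.shape)
    u[stack.analysis_mask] = u_all[stack.patient_index]
    return FuzzyLesionMap(
        ProbVolume(u, grid.spacing, grid.origin), stack.analysis_mask, tissue
    )


def combine_max(a: FuzzyLesionMap, b: FuzzyLesionMap) -> FuzzyLesionMap:
    """Voxelwise max of two fuzzy lesion maps (fuzzy-logic union)."""
    check_same_grid([a.u, b.u])
    u = np.maximum(a.u.data, b.u.data)
    return FuzzyLesionMap(
        a.u.like(u), np.logical_or(a.mask, b.mask), tissue="combined"
    )


def binarize(fuzzy: FuzzyLesionMap, params: BinarizeParams | None = None) -> np.ndarray:
    """Threshold U and optionally drop small connected components."""
    params = params or BinarizeParams()
    mask = fuzzy.u.data > params.u_threshold
    if params.min_cluster_voxels > 0 and mask.any():
        conn = {6: 1, 18: 2, 26: 3}[params.connectivity]
        labels = measure.label(mask, connectivity=conn)
        counts = np.bincount(labels.reshape(-1))
        keep = counts >= params.min_cluster_voxels
        keep[0] = False
        mask = keep[labels]
    return mask
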