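"""Prior-informed Gaussian-mixture tissue segmentation with an extra lesion class.

A single T1-like volume is segmented into GM / WM / CSF / EXTRA /
background using spatial priors and one Gaussian intensity model per
class.  The EXTRA class explicitly models abnormal tissue: its prior is
initialised as the mean of the WM and CSF priors and then refined at the
individual-patient level — after each EM fit the EXTRA posterior is
smoothed, floored, and fed back as the next EXTRA prior.  Without such a
class, abnormal voxels are absorbed into "normal" GM or WM and become
invisible to downstream outlier detection.

Segmentation here operates on spatially aligned volumes: the nonlinear
warping and bias-field machinery of full unified segmentation models is
intentionally absent (see the methods note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.special import logsumexp

from .core_io import (
    ProbVolume,
    SmoothParams,
    Volume3D,
    check_same_grid,
    gaussian_smooth,
)

logger = logging.getLogger(__name__)


class TissueClass(Enum):
    GM = "gm"
    WM = "wm"
    CSF = "csf"
    EXTRA = "extra"
    BACKGROUND = "background"


#: canonical class ordering used when stacking maps
CLASS_ORDER = (
    TissueClass.GM,
    TissueClass.WM,
    TissueClass.CSF,
    TissueClass.EXTRA,
    TissueClass.BACKGROUND,
)


class ClassMapSet:
    """An ordered set of per-class probability volumes on one grid."""

    sum_tol: float = 1e-4

    def __init__(self, maps: dict[TissueClass, ProbVolume], validate_sum: bool = True):
        self.maps = {c: maps[c] for c in CLASS_ORDER if c in maps}
        check_same_grid(self.maps.values())
        if validate_sum:
            total = self.stack().sum(axis=0)
            err = float(np.abs(total - 1.0).max())
            if err > self.sum_tol:
                raise ValueError(
                    f"per-voxel class probabilities must sum to 1 "
                    f"(max |sum-1| = {err:.2e} > {self.sum_tol})"
                )

    def __getitem__(self, c: TissueClass) -> ProbVolume:
        return self.maps[c]

    def __contains__(self, c: TissueClass) -> bool:
        return c in self.maps

    @property
    def classes(self) -> tuple[TissueClass, ...]:
        return tuple(self.maps)

    @property
    def grid(self) -> ProbVolume:
        return next(iter(self.maps.values()))

    def stack(self) -> np.ndarray:
        """(n_classes, *shape) array in :data:`CLASS_ORDER` order."""
        return np.stack([self.maps[c].data for c in self.maps])

    @classmethod
    def from_stack(cls, arr: np.ndarray, classes, grid: Volume3D, **kw):
        maps = {
            c: ProbVolume(arr[k], grid.spacing, grid.origin)
            for k, c in enumerate(classes)
        }
        return cls(maps, **kw)

    def brain_mask(self, threshold: float = 0.5) -> np.ndarray:
        """Voxels whose non-background probability mass exceeds ``threshold``."""
        tissue = sum(
            self.maps[c].data for c in self.maps if c is not TissueClass.BACKGROUND
        )
        return tissue > threshold


class PriorSet(ClassMapSet):
    """Spatial tissue priors (template probabilities), sum-to-1 within 1e-4."""

    sum_tol = 1e-4


class TissueProbabilityMaps(ClassMapSet):
    """Segmentation posteriors, sum-to-1 within 1e-6."""

    sum_tol = 1e-6


@dataclass
class GaussianClassModel:
    """One Gaussian intensity model per tissue class."""

    classes: tuple[TissueClass, ...]
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float = float("-inf")
    n_iter: int = 0
    ll_history: list = field(default_factory=list)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if np.any(self.variances <= 0):
            raise ValueError("class variances must be strictly positive")


@dataclass
class SegmentationParams:
    """Knobs of the EM segmentation and the extra-prior refinement loop.

    ``prior_floor`` keeps every class reachable everywhere (a hard-zero
    prior would forbid lesion detection at that voxel).  After each of
    the ``n_prior_updates`` outer passes the EXTRA posterior is smoothed
    at ``extra_update_fwhm_mm`` and values below ``extra_floor`` are
    zeroed before it becomes the next EXTRA prior.
    """

    em_max_iter: int = 50
    em_tol: float = 1e-6
    prior_floor: float = 1e-3
    n_prior_updates: int = 2
    extra_update_fwhm_mm: float = 6.0
    extra_floor: float = 0.15
    var_floor: float = 1e-6
    background_exclude_prior: float = 0.99
    update_extra_model: bool = False

    def __post_init__(self):
        if self.em_max_iter < 1:
            raise ValueError("em_max_iter must be >= 1")
        if not (0 <= self.prior_floor < 0.05):
            raise ValueError("prior_floor must be in [0, 0.05)")


def init_extra_prior(priors: ClassMapSet) -> ProbVolume:
    """Initial abnormal-tissue prior: the voxelwise mean of WM and CSF priors.

    The caller inserts it into the prior set and renormalizes.
    """
    wm, csf = priors[TissueClass.WM], priors[TissueClass.CSF]
    check_same_grid([wm, csf])
    return ProbVolume((wm.data + csf.data) / 2.0, wm.spacing, wm.origin)


def renormalize_priors(maps: dict[TissueClass, ProbVolume]) -> PriorSet:
    """Rescale per-voxel class values to sum to 1.

    Voxels whose total mass is zero are assigned to background.
    """
    classes = [c for c in CLASS_ORDER if c in maps]
    grid = maps[classes[0]]
    arr = np.stack([maps[c].data for c in classes])
    if arr.min() < 0:
        raise ValueError("negative class probability")
    total = arr.sum(axis=0)
    dead = total <= 0
    total = np.where(dead, 1.0, total)
    arr = arr / total
    if dead.any():
        if TissueClass.BACKGROUND not in classes:
            raise ValueError("all-zero voxel but no background class to assign it to")
        arr[:, dead] = 0.0
        arr[classes.index(TissueClass.BACKGROUND)][dead] = 1.0
    return PriorSet.from_stack(arr, classes, grid)


def with_extra_prior(priors: ClassMapSet, extra: ProbVolume | None = None) -> PriorSet:
    """Insert an EXTRA prior (default: mean of WM and CSF) and renormalize."""
    if extra is None:
        extra = init_extra_prior(priors)
    maps = dict(priors.maps)
    maps[TissueClass.EXTRA] = extra
    return renormalize_priors(maps)


def _log_normal_pdf(y: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (y - mean) ** 2 / var)


def em_segment(
    vol: Volume3D, priors: PriorSet, params: SegmentationParams | None = None
) -> tuple[TissueProbabilityMaps, GaussianClassModel]:
    """Fit the prior-weighted Gaussian mixture by EM and return posteriors.

    Responsibilities are ``prior_k(v) * Normal(y_v; mu_k, var_k)``
    normalized per voxel; class means and variances are re-estimated
    from the responsibilities until the penalized log-likelihood change
    falls below ``em_tol`` (relative) or ``em_max_iter`` is reached.
    Initialization is deterministic: moments under the priors.

    Voxels with background prior above ``background_exclude_prior`` are
    excluded from the parameter statistics (they still receive
    posteriors from the fitted model).
    """
    params = params or SegmentationParams()
    check_same_grid([vol, priors.grid])
    classes = list(priors.classes)
    y = vol.data.reshape(-1)
    pr = priors.stack().reshape(len(classes), -1)

    if params.prior_floor > 0:
        pr = pr + params.prior_floor
        pr = pr / pr.sum(axis=0)

    with np.errstate(divide="ignore"):
        log_pr = np.log(pr)

    if TissueClass.BACKGROUND in classes:
        bg = pr[classes.index(TissueClass.BACKGROUND)]
        include = bg <= params.background_exclude_prior
    else:
        include = np.ones_like(y, dtype=bool)
    if not include.any():
        raise ValueError("no voxels inside the analysis region")

    y_in = y[include]
    var_floor = max(params.var_floor, 1e-6 * float(np.var(y_in)))

    # deterministic init: prior-weighted intensity moments
    w = pr[:, include]
    wsum = w.sum(axis=1)
    global_mean, global_var = float(y_in.mean()), float(np.var(y_in))
    means = np.empty(len(classes))
    variances = np.empty(len(classes))
    for k in range(len(classes)):
        if wsum[k] > 1e-12:
            means[k] = float(w[k] @ y_in / wsum[k])
            variances[k] = float(w[k] @ (y_in - means[k]) ** 2 / wsum[k])
        else:  # class absent a priori: fall back to global moments
            means[k] = global_mean
            variances[k] = global_var
    variances = np.maximum(variances, var_floor)

    # The EXTRA model is an equal-weight mixture of the WM and CSF
    # moments: abnormal tissue may take any intensity between CSF-dark
    # and WM-bright.  Weighting by prior volume instead would centre
    # the model on the WM intensity tail (WM dwarfs CSF in volume) and
    # turn it into a "slightly-dark WM" detector that claims healthy
    # voxels.
    if (
        TissueClass.EXTRA in classes
        and not params.update_extra_model
        and TissueClass.WM in classes
        and TissueClass.CSF in classes
    ):
        m_wm = means[classes.index(TissueClass.WM)]
        m_csf = means[classes.index(TissueClass.CSF)]
        v_wm = variances[classes.index(TissueClass.WM)]
        v_csf = variances[classes.index(TissueClass.CSF)]
        ke = classes.index(TissueClass.EXTRA)
        means[ke] = 0.5 * (m_wm + m_csf)
        variances[ke] = max(
            0.5 * (v_wm + v_csf) + 0.25 * (m_wm - m_csf) ** 2, var_floor
        )

    ll_history: list[float] = []
    log_resp_in = None
    for it in range(params.em_max_iter):
        # E-step on included voxels
        log_joint = log_pr[:, include] + np.stack(
            [_log_normal_pdf(y_in, means[k], variances[k]) for k in range(len(classes))]
        )
        log_norm = logsumexp(log_joint, axis=0)
        ll = float(log_norm.sum())
        ll_history.append(ll)
        log_resp_in = log_joint - log_norm
        resp = np.exp(log_resp_in)

        if len(ll_history) > 1:
            prev = ll_history[-2]
            if abs(ll - prev) <= params.em_tol * (abs(prev) + 1e-12):
                break

        # M-step; the EXTRA model stays at its broad initialization by
        # default so the abnormal class cannot collapse onto a normal
        # tissue mode and siphon healthy voxels
        nk = resp.sum(axis=1)
        for k in range(len(classes)):
            if classes[k] is TissueClass.EXTRA and not params.update_extra_model:
                continue
            if nk[k] < 1e-8:
                logger.debug(
                    "class %s has ~zero responsibility; keeping previous parameters",
                    classes[k].value,
                )
                continue
            means[k] = float(resp[k] @ y_in / nk[k])
            variances[k] = max(
                float(resp[k] @ (y_in - means[k]) ** 2 / nk[k]), var_floor
            )

    # final posteriors over the whole grid with the fitted model
    log_joint_all = log_pr + np.stack(
        [_log_normal_pdf(y, means[k], variances[k]) for k in range(len(classes))]
    )
    post = np.exp(log_joint_all - logsumexp(log_joint_all, axis=0))
    post = post.reshape((len(classes),) + vol.shape)

    model = GaussianClassModel(
        tuple(classes),
        means,
        variances,
        log_likelihood=ll_history[-1],
        n_iter=len(ll_history),
        ll_history=ll_history,
    )
    tpm = TissueProbabilityMaps.from_stack(post, classes, vol)
    return tpm, model


def optimize_extra_prior(
    vol: Volume3D, priors: PriorSet, params: SegmentationParams | None = None
) -> tuple[TissueProbabilityMaps, ProbVolume, GaussianClassModel]:
    """Segment with iterative refinement of the abnormal-tissue prior.

    Each outer pass runs :func:`em_segment`, then rebuilds the EXTRA
    prior from the smoothed EXTRA posterior (values below
    ``extra_floor`` zeroed) and renormalizes the prior set.  Returns the
    final posteriors, the final EXTRA prior, and the final class model.
    """
    params = params or SegmentationParams()
    if TissueClass.EXTRA not in priors:
        raise ValueError("priors must include an EXTRA class (see with_extra_prior)")
    current = priors
    tpm = model = None
    extra_prior = current[TissueClass.EXTRA]
    for i in range(max(1, params.n_prior_updates)):
        tpm, model = em_segment(vol, current, params)
        smoothed = gaussian_smooth(
            tpm[TissueClass.EXTRA], SmoothParams(params.extra_update_fwhm_mm)
        )
        data = np.where(smoothed.data >= params.extra_floor, smoothed.data, 0.0)
        extra_prior = ProbVolume(data, smoothed.spacing, smoothed.origin)
        logger.info(
            "extra-prior update %d: mass %.1f voxels (>= %.2f), EM iters %d",
            i + 1,
            float(data.sum()),
            params.extra_floor,
            model.n_iter,
        )
        maps = dict(priors.maps)
        maps[TissueClass.EXTRA] = extra_prior
        current = renormalize_priors(maps)
    return tpm, current[TissueClass.EXTRA], model
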