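"""Volume containers, NIfTI I/O, grid checks and Gaussian smoothing.

All pipeline stages exchange :class:`Volume3D` / :class:`ProbVolume`
objects: a 3D scalar array plus voxel spacing and origin in mm.  The
pipeline is deliberately resampling-free — every stage refuses grids
that do not match instead of silently interpolating, because the
voxelwise patient-versus-controls comparison downstream assumes exact
spatial correspondence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: conversion between a Gaussian FWHM and its standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: kernel support used by :func:`gaussian_smooth`, in standard deviations
SMOOTH_TRUNCATE_SD = 4.0

GRID_ATOL_MM = 1e-4


class GridMismatchError(ValueError):
    """Two volumes do not share shape and voxel spacing."""


class VolumeFormatError(ValueError):
    """A file on disk is not a readable 3D scalar image."""


@dataclass
class Volume3D:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    spacing
        Per-axis voxel size in mm, all strictly positive.
    origin
        Per-axis offset of the first voxel centre in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def like(self, data: np.ndarray) -> "Volume3D":
        """A new volume with the same grid and the given data."""
        return type(self)(np.asarray(data), self.spacing, self.origin)


@dataclass
class ProbVolume(Volume3D):
    """A :class:`Volume3D` whose voxels are probabilities in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        lo, hi = float(self.data.min(initial=0.0)), float(self.data.max(initial=0.0))
        if lo < -1e-9 or hi > 1.0 + 1e-9:
            raise ValueError(f"probability volume out of [0, 1]: range [{lo}, {hi}]")
        np.clip(self.data, 0.0, 1.0, out=self.data)


@dataclass
class SmoothParams:
    """Gaussian smoothing kernel width; the pipeline default is 8 mm FWHM."""

    fwhm_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError(f"fwhm_mm must be >= 0, got {self.fwhm_mm}")


def read_volume(path, as_prob: bool = False) -> Volume3D:
    """Load a 3D NIfTI-1 image.

    Header intensity scaling is applied (nibabel's ``get_fdata``).  NaNs
    in the source are replaced by 0 and counted in the log, because the
    cohort covariance downstream is undefined under NaN.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, header declares {len(img.shape)} dimensions"
        )
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    n_nan = int(np.isnan(data).sum())
    if n_nan:
        logger.warning("%s: replaced %d NaN voxels with 0", path, n_nan)
        data = np.nan_to_num(data, nan=0.0)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    cls = ProbVolume if as_prob else Volume3D
    return cls(data, tuple(float(z) for z in zooms), origin)


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as 32-bit float NIfTI-1.

    The affine is diagonal in the voxel spacing with the origin as
    translation; voxel order as stored is authoritative throughout the
    pipeline, so no reorientation is applied.
    """
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def check_same_grid(vols) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid.

    Shapes must be identical and spacings equal within 1e-4 mm.
    """
    vols = list(vols)
    if not vols:
        raise ValueError("empty volume collection")
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape:
            raise GridMismatchError(f"shape mismatch: {ref.shape} vs {v.shape}")
        if not np.allclose(v.spacing, ref.spacing, atol=GRID_ATOL_MM, rtol=0.0):
            raise GridMismatchError(f"spacing mismatch: {ref.spacing} vs {v.spacing} mm")


def gaussian_smooth(vol: Volume3D, params: SmoothParams) -> Volume3D:
    """Smooth with an isotropic-in-mm Gaussian kernel.

    The per-axis sigma in voxels is ``fwhm_mm / (spacing * 2*sqrt(2 ln 2))``.
    Reflecting (mirror) boundaries are used so that every output voxel is
    a convex combination of input voxels: probability maps stay in [0, 1].
    The kernel is truncated at 4 sigma.
    """
    if params.fwhm_mm == 0:
        return vol.like(vol.data.copy())
    sigma_vox = [params.fwhm_mm * FWHM_TO_SIGMA / s for s in vol.spacing]
    out = ndimage.gaussian_filter(
        vol.data, sigma=sigma_vox, mode="reflect", truncate=SMOOTH_TRUNCATE_SD
    )
    if isinstance(vol, ProbVolume):
        # convex combination can exceed [0,1] only by float round-off
        out = np.clip(out, 0.0, 1.0)
    return vol.like(out)
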