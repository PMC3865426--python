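"""Synthetic T1-like brain phantoms with known lesion ground truth.

The generator stands in for real template priors, control scans and
patient scans so the whole pipeline can be exercised end to end with a
known answer.  It emulates the statistical structure the method relies
on:

* T1-like intensity ordering CSF < GM < WM;
* smooth inter-subject anatomical variability in controls, modelled as
  a random smooth displacement field applied to the class geometry
  (pure voxel noise would understate the spatial correlation that the
  cohort comparison's null distribution depends on).  Because every
  stage assumes volumes already aligned to the template — spatial
  normalization happens upstream and is out of scope — the default
  displacement magnitude represents the sub-voxel variability that
  remains *after* normalization, not raw anatomical differences;
* tumours of configurable size (the clinically motivated range is
  1.5-23 cm^3), location and intensity, with spatially correlated
  texture — including the hard case of lesions isointense with grey
  matter.

Anatomy is an ellipsoidal brain with a WM core, a GM shell between the
two surfaces, and ellipsoidal CSF ventricles inside the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import FWHM_TO_SIGMA, ProbVolume, SmoothParams, Volume3D, gaussian_smooth
from .segmentation import CLASS_ORDER, PriorSet, TissueClass, renormalize_priors


class GeometryError(ValueError):
    """A geometric constraint of the phantom is violated."""


@dataclass
class TemplateGeometry:
    """Ellipsoidal brain geometry, all sizes in mm.

    The WM core must lie strictly inside the brain ellipsoid and every
    ventricle inside the WM core.  ``prior_blur_fwhm_mm`` softens the
    hard class boundaries into probabilistic priors.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_radii_mm: tuple[float, float, float] = (36.0, 38.0, 34.0)
    wm_radii_mm: tuple[float, float, float] = (31.0, 33.0, 29.0)
    ventricle_radii_mm: tuple[float, float, float] = (6.0, 10.0, 6.0)
    ventricle_offsets_mm: tuple = ((-9.0, 0.0, 2.0), (9.0, 0.0, 2.0))
    prior_blur_fwhm_mm: float = 4.0

    def __post_init__(self):
        if not all(w < b for w, b in zip(self.wm_radii_mm, self.brain_radii_mm)):
            raise GeometryError("WM core must lie strictly inside the brain ellipsoid")
        for off in self.ventricle_offsets_mm:
            # the ventricle's bounding ellipsoid must fit inside the WM core
            reach = [
                (abs(o) + r) / w
                for o, r, w in zip(off, self.ventricle_radii_mm, self.wm_radii_mm)
            ]
            if max(reach) > 1.0:
                raise GeometryError(f"ventricle at offset {off} extends outside WM core")

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing_mm)

    def coords_mm(self) -> list[np.ndarray]:
        """Voxel-centre coordinates in mm, relative to the grid centre."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.shape, self.spacing_mm)
        ]
        return np.meshgrid(*axes, indexing="ij")


@dataclass
class AppearanceModel:
    """Intensity model of the phantom, arbitrary units roughly in [0, 1].

    ``class_means`` must keep the T1-like ordering CSF < GM < WM;
    ``subject_jitter_sd`` perturbs the class means per subject;
    ``warp_jitter_mm`` sets the RMS magnitude of the smooth random
    displacement emulating anatomical variability; ``noise_sd`` is
    additive voxel noise.
    """

    class_means: dict = field(
        default_factory=lambda: {
            TissueClass.CSF: 0.20,
            TissueClass.GM: 0.50,
            TissueClass.WM: 0.80,
            TissueClass.BACKGROUND: 0.02,
        }
    )
    class_sds: dict = field(
        default_factory=lambda: {
            TissueClass.CSF: 0.04,
            TissueClass.GM: 0.04,
            TissueClass.WM: 0.04,
            TissueClass.BACKGROUND: 0.01,
        }
    )
    subject_jitter_sd: float = 0.015
    warp_jitter_mm: float = 0.3
    warp_field_fwhm_mm: float = 12.0
    noise_sd: float = 0.02

    def __post_init__(self):
        m = self.class_means
        if not (m[TissueClass.CSF] < m[TissueClass.GM] < m[TissueClass.WM]):
            raise ValueError("class means must be ordered CSF < GM < WM (T1-like)")
        if any(s < 0 for s in self.class_sds.values()) or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


@dataclass
class LesionSpec:
    """An ellipsoidal lesion with correlated texture.

    ``center_mm`` is relative to the grid centre.  ``intensity_mean``
    is ignored when ``isointense_to`` names a tissue class, in which
    case the lesion mimics that class's (subject-jittered) mean — the
    hard case for segmentation.  ``texture_fwhm_mm`` sets the spatial
    correlation of the lesion texture; heterogeneous, diffuse signal is
    what defeats a single segmentation pass and motivates recursion.
    """

    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    intensity_mean: float = 0.20
    intensity_sd: float = 0.05
    texture_fwhm_mm: float = 6.0
    isointense_to: TissueClass | None = None

    @property
    def volume_cm3(self) -> float:
        """Nominal ellipsoid volume implied by the radii."""
        return 4.0 / 3.0 * np.pi * float(np.prod(self.radii_mm)) / 1000.0


def _ellipsoid(coords, center_mm, radii_mm) -> np.ndarray:
    q = sum(
        ((c - o) / r) ** 2 for c, o, r in zip(coords, center_mm, radii_mm)
    )
    return q <= 1.0


def make_template_priors(geom: TemplateGeometry | None = None) -> PriorSet:
    """Deterministic template priors over {GM, WM, CSF, background}.

    Hard ellipsoid labels (GM shell, WM core, CSF ventricles) are
    blurred at ``prior_blur_fwhm_mm`` and renormalized so every voxel
    is a probability distribution over classes.
    """
    geom = geom or TemplateGeometry()
    coords = geom.coords_mm()
    brain = _ellipsoid(coords, (0, 0, 0), geom.brain_radii_mm)
    wm_core = _ellipsoid(coords, (0, 0, 0), geom.wm_radii_mm)
    csf = np.zeros(geom.shape, dtype=bool)
    for off in geom.ventricle_offsets_mm:
        csf |= _ellipsoid(coords, off, geom.ventricle_radii_mm)
    labels = {
        TissueClass.GM: brain & ~wm_core,
        TissueClass.WM: wm_core & ~csf,
        TissueClass.CSF: csf,
        TissueClass.BACKGROUND: ~brain,
    }
    smooth = SmoothParams(geom.prior_blur_fwhm_mm)
    maps = {}
    for c, lab in labels.items():
        vol = ProbVolume(lab.astype(float), geom.spacing_mm)
        maps[c] = gaussian_smooth(vol, smooth)
    return renormalize_priors(maps)


def _smooth_noise(rng, shape, spacing, fwhm_mm) -> np.ndarray:
    """Unit-RMS spatially correlated Gaussian noise."""
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in spacing]
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="reflect")
    rms = np.sqrt(np.mean(f**2))
    return f / max(rms, 1e-12)


def _warp_priors(priors: PriorSet, app: AppearanceModel, rng) -> PriorSet:
    """Apply a smooth random displacement field to the class geometry."""
    grid = priors.grid
    shape, spacing = grid.shape, grid.spacing
    if app.warp_jitter_mm == 0:
        return priors
    disp = [
        _smooth_noise(rng, shape, spacing, app.warp_field_fwhm_mm)
        * app.warp_jitter_mm
        / s
        for s in spacing
    ]
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    coords = [i + d for i, d in zip(idx, disp)]
    maps = {}
    for c in priors.classes:
        warped = ndimage.map_coordinates(
            priors[c].data, coords, order=1, mode="nearest"
        )
        maps[c] = ProbVolume(np.clip(warped, 0, 1), spacing, grid.origin)
    return renormalize_priors(maps)


def _render_intensity(tissue: PriorSet, app: AppearanceModel, rng):
    """Intensities from the subject's hard tissue labels plus noise.

    Each voxel takes the (subject-jittered) mean of its most probable
    class plus within-class and global noise; partial-volume mixing is
    deliberately not modelled.
    """
    means = {
        c: app.class_means[c] + rng.normal(0.0, app.subject_jitter_sd)
        for c in app.class_means
    }
    stack = tissue.stack()
    classes = tissue.classes
    labels = np.argmax(stack, axis=0)
    img = np.zeros(tissue.grid.shape)
    sd = np.zeros_like(img)
    for k, c in enumerate(classes):
        sel = labels == k
        img[sel] = means[c]
        sd[sel] = app.class_sds[c]
    img += rng.standard_normal(img.shape) * sd
    img += rng.standard_normal(img.shape) * app.noise_sd
    return img, means


def simulate_control(
    priors: PriorSet, app: AppearanceModel | None = None, seed: int = 0
) -> tuple[Volume3D, PriorSet]:
    """One control subject: intensity volume plus true tissue maps.

    The subject's anatomy is the template warped by a random smooth
    displacement field; the returned tissue maps are that subject's
    true (warped) class probabilities, not the template's.
    """
    app = app or AppearanceModel()
    rng = np.random.default_rng(seed)
    tissue = _warp_priors(priors, app, rng)
    img, _ = _render_intensity(tissue, app, rng)
    grid = priors.grid
    return Volume3D(img, grid.spacing, grid.origin), tissue


def simulate_patient(
    priors: PriorSet,
    app: AppearanceModel | None = None,
    lesion: LesionSpec | None = None,
    seed: int = 0,
) -> tuple[Volume3D, np.ndarray]:
    """One lesioned patient: intensity volume plus ground-truth mask.

    The lesion replaces the tissue signal inside an ellipsoid with its
    own intensity model: a constant mean (or the subject's mean of the
    ``isointense_to`` class) plus spatially correlated texture of the
    requested amplitude.  The lesion must lie inside the brain.
    """
    app = app or AppearanceModel()
    lesion = lesion or LesionSpec()
    rng = np.random.default_rng(seed)
    tissue = _warp_priors(priors, app, rng)
    img, means = _render_intensity(tissue, app, rng)
    grid = priors.grid

    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(grid.shape, grid.spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    truth = _ellipsoid(coords, lesion.center_mm, lesion.radii_mm)
    if not truth.any():
        raise GeometryError("lesion does not cover any voxel")
    brain = tissue.brain_mask(0.5)
    if (truth & ~brain).sum() > 0:
        raise GeometryError("lesion extends outside the brain")

    if lesion.isointense_to is not None:
        base = means[lesion.isointense_to]
    else:
        base = lesion.intensity_mean
    texture = _smooth_noise(rng, grid.shape, grid.spacing, lesion.texture_fwhm_mm)
    img[truth] = base + lesion.intensity_sd * texture[truth]
    img[truth] += rng.standard_normal(int(truth.sum())) * app.noise_sd
    return Volume3D(img, grid.spacing, grid.origin), truth
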