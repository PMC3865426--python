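"""Canonical synthetic study conditions for end-to-end evaluation.

These helpers assemble everything an end-to-end run needs — template
priors, a segmented-and-smoothed control cohort, and a lesioned
patient — under fixed, documented conditions:

* 12 controls on a 48^3 grid at 2 mm isotropic spacing;
* an "easy" scenario: a dark (CSF-like) 10 mm-radius spherical lesion
  deep in the white matter, which the first segmentation pass already
  assigns to the extra class;
* a "hard" scenario: a grey-matter-isointense, textured lesion
  straddling the WM/GM boundary, which a single pass misclassifies as
  normal grey matter and only the recursive pass recovers.

Controls pass through the same segmentation used for the patient (not
the generator's ground truth), mirroring a pipeline in which every
subject is processed identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ProbVolume, SmoothParams, Volume3D, gaussian_smooth
from .driver import ControlCohort
from .segmentation import (
    PriorSet,
    SegmentationParams,
    TissueClass,
    optimize_extra_prior,
    with_extra_prior,
)
from .synthetic import (
    AppearanceModel,
    LesionSpec,
    TemplateGeometry,
    make_template_priors,
    simulate_control,
    simulate_patient,
)

DEFAULT_N_CONTROLS = 12

#: dark CSF-like sphere, 10 mm radius (~4.2 cm^3), deep white matter
DARK_LESION = LesionSpec(
    center_mm=(0.0, 14.0, 0.0),
    radii_mm=(10.0, 10.0, 10.0),
    intensity_mean=0.20,
    intensity_sd=0.03,
    texture_fwhm_mm=6.0,
)

#: GM-isointense heterogeneous lesion (~2.5 cm^3) spreading tangentially
#: within the cortical GM shell — the empty-extra-prior failure case:
#: large GM-matched texture patches are spatially and intensity-wise
#: plausible grey matter, so a single segmentation pass misclassifies
#: them as intact GM and only their abnormal neighbours seed detection
ISOINTENSE_LESION = LesionSpec(
    center_mm=(0.0, 32.0, 0.0),
    radii_mm=(14.0, 3.0, 14.0),
    intensity_sd=0.08,
    texture_fwhm_mm=12.0,
    isointense_to=TissueClass.GM,
)


@dataclass
class StudyConditions:
    """Template, appearance and cohort-size settings shared by scenarios."""

    geometry: TemplateGeometry = field(default_factory=TemplateGeometry)
    appearance: AppearanceModel = field(default_factory=AppearanceModel)
    n_controls: int = DEFAULT_N_CONTROLS
    smooth: SmoothParams = field(default_factory=SmoothParams)
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)


def build_control_cohort(
    priors: PriorSet,
    conditions: StudyConditions,
    seed: int = 0,
) -> ControlCohort:
    """Simulate, segment and smooth the control cohort.

    Control ``k`` uses seed ``seed*1000 + k``.  Each control is
    segmented with the same extra-class prior set used for patients,
    then its GM and WM posteriors are smoothed.
    """
    seg_priors = with_extra_prior(priors)
    gm, wm = [], []
    for k in range(conditions.n_controls):
        vol, _ = simulate_control(priors, conditions.appearance, seed=seed * 1000 + k)
        tpm, _, _ = optimize_extra_prior(vol, seg_priors, conditions.seg_params)
        gm.append(gaussian_smooth(tpm[TissueClass.GM], conditions.smooth))
        wm.append(gaussian_smooth(tpm[TissueClass.WM], conditions.smooth))
    return ControlCohort(gm=gm, wm=wm)


def build_patient(
    priors: PriorSet,
    conditions: StudyConditions,
    lesion: LesionSpec | None,
    seed: int = 0,
) -> tuple[Volume3D, np.ndarray | None]:
    """A lesioned patient volume plus truth mask (or a lesion-free one)."""
    if lesion is None:
        vol, _ = simulate_control(priors, conditions.appearance, seed=seed)
        return vol, None
    return simulate_patient(priors, conditions.appearance, lesion, seed=seed)


def default_conditions() -> StudyConditions:
    return StudyConditions()


def template_priors(conditions: StudyConditions | None = None) -> PriorSet:
    conditions = conditions or StudyConditions()
    return make_template_priors(conditions.geometry)
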