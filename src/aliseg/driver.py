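"""Pipeline orchestration: one lesion-identification pass and its recursion.

One pass = segment the patient with the extra-class prior, smooth the
GM and WM posteriors at 8 mm FWHM, compare each against the controls'
smoothed maps with the fuzzy outlier detector, combine the two fuzzy
lesion images with the max operator, and threshold.  In recursive mode
the fuzzy set of pass 1 becomes the patient-specific extra-class prior
of pass 2: a lesion the first segmentation misclassified as normal
tissue (the empty-extra-prior failure, typical of lesions isointense
with grey matter) repopulates the prior and is recovered.  Two passes
are near-optimal; more are allowed but add little and risk
misclassifying intact tissue.

Everything here is a pure function of its inputs — no randomness, so
identical inputs give bitwise-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import ProbVolume, SmoothParams, Volume3D, check_same_grid, gaussian_smooth
from .fcp import (
    BinarizeParams,
    CohortStack,
    FCPParams,
    FuzzyLesionMap,
    binarize,
    combine_max,
    detect_tissue_outliers,
)
from .segmentation import (
    GaussianClassModel,
    PriorSet,
    SegmentationParams,
    TissueClass,
    TissueProbabilityMaps,
    optimize_extra_prior,
    renormalize_priors,
    with_extra_prior,
)

logger = logging.getLogger(__name__)


@dataclass
class ControlCohort:
    """Controls' segmented and smoothed GM and WM probability maps."""

    gm: list[ProbVolume]
    wm: list[ProbVolume]

    def __post_init__(self):
        if len(self.gm) != len(self.wm):
            raise ValueError("need one GM and one WM map per control")
        if len(self.gm) < 2:
            raise ValueError("need at least 2 controls (FCP needs N_sub >= 3)")
        check_same_grid(self.gm + self.wm)

    @property
    def n_controls(self) -> int:
        return len(self.gm)


@dataclass
class RecursionParams:
    """Recursion depth and fuzzy-to-prior feedback rule.

    The fed-back extra prior is ``min(U, prior_cap)``: a cap below 1
    keeps the extra class refutable, so the second segmentation can
    still reject false positives.  ``carry_smoothing`` optionally
    smooths the fuzzy set before feedback (off by default — it already
    derives from smoothed maps).
    """

    n_rounds: int = 2
    prior_cap: float = 0.85
    carry_smoothing: float = 0.0

    def __post_init__(self):
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not (0 < self.prior_cap < 1):
            raise ValueError("prior_cap must be in (0, 1)")
        if self.n_rounds > 2:
            logger.warning(
                "n_rounds=%d: more than two passes is unvalidated and may "
                "misclassify intact tissue", self.n_rounds,
            )


@dataclass
class AliRoundResult:
    """Artifacts of one pipeline pass."""

    round_index: int
    posteriors: TissueProbabilityMaps
    extra_prior: ProbVolume
    model: GaussianClassModel
    fuzzy_gm: FuzzyLesionMap
    fuzzy_wm: FuzzyLesionMap
    fuzzy: FuzzyLesionMap
    mask: np.ndarray
    settings: dict = field(default_factory=dict)


def run_ali(
    vol: Volume3D,
    priors: PriorSet,
    cohort: ControlCohort,
    seg_params: SegmentationParams | None = None,
    fcp_params: FCPParams | None = None,
    smooth_params: SmoothParams | None = None,
    binarize_params: BinarizeParams | None = None,
    round_index: int = 1,
) -> AliRoundResult:
    """One full pass: segmentation, smoothing, outlier detection, threshold.

    ``priors`` must already contain the EXTRA class (see
    :func:`aliseg.segmentation.with_extra_prior` for the default
    mean-of-WM-and-CSF initialisation).
    """
    seg_params = seg_params or SegmentationParams()
    fcp_params = fcp_params or FCPParams()
    smooth_params = smooth_params or SmoothParams()
    binarize_params = binarize_params or BinarizeParams()
    check_same_grid([vol, priors.grid] + cohort.gm)

    posteriors, extra_prior, model = optimize_extra_prior(vol, priors, seg_params)

    fuzzy_by_tissue = {}
    for tissue, cls, controls in (
        ("gm", TissueClass.GM, cohort.gm),
        ("wm", TissueClass.WM, cohort.wm),
    ):
        patient = gaussian_smooth(posteriors[cls], smooth_params)
        stack = CohortStack(maps=controls + [patient], patient_index=len(controls))
        fuzzy_by_tissue[tissue] = detect_tissue_outliers(stack, fcp_params, tissue)
    fuzzy = combine_max(fuzzy_by_tissue["gm"], fuzzy_by_tissue["wm"])
    mask = binarize(fuzzy, binarize_params)

    u_in = fuzzy.u.data[fuzzy.mask]
    logger.info(
        "round %d: EM iters %d, extra-prior mass %.1f, U quantiles "
        "[50%% %.3f, 95%% %.3f, max %.3f], mask %d voxels",
        round_index, model.n_iter, float(extra_prior.data.sum()),
        *np.percentile(u_in, [50, 95]), u_in.max(), int(mask.sum()),
    )
    return AliRoundResult(
        round_index=round_index,
        posteriors=posteriors,
        extra_prior=extra_prior,
        model=model,
        fuzzy_gm=fuzzy_by_tissue["gm"],
        fuzzy_wm=fuzzy_by_tissue["wm"],
        fuzzy=fuzzy,
        mask=mask,
        settings=dict(
            seg=vars(seg_params), fcp=vars(fcp_params),
            smooth=vars(smooth_params), binarize=vars(binarize_params),
        ),
    )


def fuzzy_to_extra_prior(
    fuzzy: FuzzyLesionMap,
    base_priors: PriorSet,
    params: RecursionParams | None = None,
) -> PriorSet:
    """Recycle a fuzzy lesion map as the patient-specific extra prior.

    EXTRA prior = ``min(U, prior_cap)``; the remaining per-voxel mass is
    split over the other classes proportionally to their base priors.
    """
    params = params or RecursionParams()
    check_same_grid([fuzzy.u, base_priors.grid])
    u = fuzzy.u
    if params.carry_smoothing > 0:
        u = gaussian_smooth(u, SmoothParams(params.carry_smoothing))
    extra = np.minimum(u.data, params.prior_cap)
    grid = base_priors.grid
    others = [c for c in base_priors.classes if c is not TissueClass.EXTRA]
    base = np.stack([base_priors[c].data for c in others])
    base_sum = base.sum(axis=0)
    # voxels with no base tissue mass: hand the remainder to background
    safe = np.where(base_sum > 0, base_sum, 1.0)
    scale = (1.0 - extra) / safe
    maps = {}
    for k, c in enumerate(others):
        data = base[k] * scale
        if c is TissueClass.BACKGROUND:
            data = np.where(base_sum > 0, data, 1.0 - extra)
        maps[c] = ProbVolume(np.clip(data, 0, 1), grid.spacing, grid.origin)
    maps[TissueClass.EXTRA] = ProbVolume(extra, grid.spacing, grid.origin)
    return renormalize_priors(maps)


def run_recursive_ali(
    vol: Volume3D,
    priors: PriorSet,
    cohort: ControlCohort,
    seg_params: SegmentationParams | None = None,
    fcp_params: FCPParams | None = None,
    smooth_params: SmoothParams | None = None,
    binarize_params: BinarizeParams | None = None,
    recursion: RecursionParams | None = None,
) -> list[AliRoundResult]:
    """Run the pipeline recursively; the default is two rounds.

    ``priors`` may omit the EXTRA class; round 1 then uses the default
    mean-of-WM-and-CSF extra prior.  Each later round re-runs the full
    pass with the previous round's fuzzy set fed back as the extra
    prior.  Returns the results of all rounds in order.
    """
    recursion = recursion or RecursionParams()
    if TissueClass.EXTRA in priors:
        round_priors = priors
        base = PriorSet(
            {c: priors[c] for c in priors.classes if c is not TissueClass.EXTRA},
            validate_sum=False,
        )
    else:
        base = priors
        round_priors = with_extra_prior(priors)
    results = []
    for k in range(recursion.n_rounds):
        result = run_ali(
            vol, round_priors, cohort,
            seg_params, fcp_params, smooth_params, binarize_params,
            round_index=k + 1,
        )
        results.append(result)
        if k + 1 < recursion.n_rounds:
            round_priors = fuzzy_to_extra_prior(result.fuzzy, base, recursion)
    return results
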