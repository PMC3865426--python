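# Methods

This note documents the models, the parameter choices that matter, the
synthetic phantom's scope, and the numerical conventions used by
`aliseg`.  Nothing here reports an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Tissue segmentation with an extra class

A single scalar volume is modelled as a prior-weighted Gaussian mixture
over {GM, WM, CSF, EXTRA, background}: the posterior responsibility of
class *k* at voxel *v* is proportional to `prior_k(v) · N(y_v; μ_k, σ_k²)`,
with means and variances re-estimated by EM until the penalized
log-likelihood changes by less than `em_tol` (relative, default 1e-6) or
`em_max_iter` (50) is reached.  Initialization is deterministic —
prior-weighted intensity moments — so segmentation is a pure function
of its inputs.  Voxels whose background prior exceeds 0.99 are excluded
from the parameter statistics but still receive posteriors.

Design choices that were genuinely open:

* **Aligned-volume scope.**  The full unified segmentation model couples
  segmentation with nonlinear warping and bias-field estimation.  Here
  the novelty of interest is the extra class and its recursive
  refinement, so segmentation operates on spatially aligned volumes and
  the tool refuses mismatched grids rather than resampling.
* **Extra-class intensity model.**  Abnormal tissue may take any
  intensity between CSF-dark and WM-bright, so the EXTRA class is given
  an equal-weight mixture of the WM and CSF moments: mean
  `(μ_WM+μ_CSF)/2`, variance `(σ_WM²+σ_CSF²)/2 + (μ_WM−μ_CSF)²/4`.
  Weighting by prior volume instead would centre the model just below
  the WM mode (WM dwarfs CSF in volume) and turn it into a
  "slightly-dark-WM" detector that claims healthy tissue.  The model is
  *held fixed* during the M-step (`update_extra_model=False`): letting
  it adapt makes it collapse onto the nearest normal tissue mode and
  siphon a third of that class's posterior.
* **Prior floor** (`prior_floor=1e-3`): added to every class prior so a
  hard zero can never forbid lesion detection at a voxel.
* **Extra-prior refinement** (`n_prior_updates=2`): after each EM fit
  the EXTRA posterior is smoothed at `extra_update_fwhm_mm=6` mm and
  values below `extra_floor=0.15` are zeroed before becoming the next
  EXTRA prior.  The floor's role is asymmetric: genuine lesions produce
  compact posterior blobs that survive smoothing (core values ≳0.5),
  while scattered single-voxel intensity outliers in healthy tissue are
  diluted below the floor and pruned.  0.15 was chosen (from a scan of
  smoothing ∈ {4,6,8} mm × floor ∈ {0.10,…,0.35} against the lesion-free
  null and the smallest in-scope lesion, 1.5 cm³) as the lowest floor
  that keeps the null's extra-class mass well under 1 % of brain volume;
  lower floors let boundary residue persist, higher floors throttle the
  recursive growth of the extra prior into diffuse lesion parts.  Two
  refinement passes follow the observation that further passes are
  ineffective once the extra prior has collapsed.

## Fuzzy outlier detection (FCP)

Fixed prototypes: `V_kj = α` if `k=j` else 0, one cluster per subject.
Distances use the **sample covariance (divisor N_sub−1)** — the unique
divisor under which the covariance form and the leave-one-out mean form
are algebraically identical (`cov(P, V_j) = α (P_j − P̄)/(N−1)`); a
dedicated oracle test pins this equivalence to 1e-10.  Defaults:
α = −0.5 (negative → abnormally *low* tissue probability is targeted),
λ = −4, maps smoothed at 8 mm FWHM before comparison.  Memberships are
computed in log space so strongly negative λ cannot overflow, with
distances floored at `d_epsilon=1e-12`.

The analysis mask defaults to voxels where the control-mean tissue
probability exceeds 0.01: outside tissue every subject's probability is
≈0 and membership is uninformative noise.  GM and WM are processed
independently and combined with the fuzzy `max`; CSF is not used.
Binarization thresholds U at 0.3 by default, with an optional
connected-component extent filter (26-connectivity default).

## Recursion

Round 1 runs with the default extra prior (mean of WM and CSF priors,
renormalized).  Each later round replaces the EXTRA prior with
`min(U, prior_cap)` from the previous round's combined fuzzy map,
distributing the remaining per-voxel mass over the other classes
proportionally to their template priors.  `prior_cap=0.85` keeps the
extra class refutable — a prior of 1 would make it irrefutable and
destroy the segmentation's ability to reject false positives.  The
default is two rounds; more are permitted but warned against (they are
slow and can misclassify intact tissue).  The fed-back map is not
re-smoothed by default (`carry_smoothing=0`): it already derives from
8 mm-smoothed maps.

## The synthetic phantom

Anatomy is an ellipsoidal brain (semi-axes 36×38×34 mm) with a WM core
(31×33×29 mm), a GM shell between the two surfaces (~37 % of brain
voxels), and two ellipsoidal CSF ventricles, on a 48³ grid at 2 mm
isotropic spacing; the brain keeps a ≥8 mm margin to the volume edge so
smoothing and warping see no boundary artifacts.  Hard class labels are
blurred at 4 mm FWHM into probabilistic priors.  Intensities are
rendered from each subject's hard (argmax) labels — T1-like means
CSF 0.20 < GM 0.50 < WM 0.80, within-class SD 0.04, global noise SD
0.02, per-subject mean jitter SD 0.015.  Partial-volume mixing is
deliberately not modelled.

Inter-subject variability is a smooth random displacement field (12 mm
correlation length) applied to the class geometry before rendering —
pure voxel noise would understate the spatial correlation that the
cohort comparison's null behaviour depends on.  Its default magnitude,
**0.5 mm RMS**, represents the *residual* variability between subjects
that have already been spatially normalized to the template (alignment
is a precondition of the whole pipeline, and normalization is out of
scope here), not raw anatomical differences.  The magnitude is pinned
by an explicit calibration: at a cohort size of 12 controls a fixed
U > 0.3 threshold must stay silent on healthy subjects, which bounds
the admissible boundary-shift tail (max shift × smoothed-map gradient
below the ≈0.17 probability deviation that maps to U = 0.3 at
N_sub = 13).  With larger cohorts, or a raised threshold — advisable
for small cohorts — proportionally larger variability is tolerable.

Lesions are ellipsoids that replace the tissue signal with a mean (or
the subject's GM mean, for the isointense case) plus spatially
correlated Gaussian texture.  Canonical scenarios
(`aliseg.scenarios`):

* **Dark lesion** — 10 mm-radius sphere (4.2 cm³) in deep WM at
  CSF-like intensity 0.20: the easy case; one pass suffices.
* **GM-isointense lesion** — a flat ellipsoid (14×3×14 mm, 2.5 cm³)
  spreading tangentially within the cortical GM shell, texture SD 0.08
  at 12 mm correlation.  Large GM-matched texture patches are spatially
  and intensity-wise plausible grey matter, so one segmentation pass
  misclassifies them as intact GM and the extra class covers well under
  half of the lesion; their abnormal neighbours seed the fuzzy map, and
  feeding it back as the round-2 extra prior recovers them.  This is
  the scenario on which the recursive pass consistently matches or
  exceeds the standard pass.

Controls destined for FCP are passed through the *same* segmentation
used for patients (not the generator's ground truth), so that every
subject traverses identical processing.

What passing tests on this phantom do **not** show: robustness to real
misregistration, bias fields, partial volume, cortical folding, mass
effect, or multi-contrast appearance — none of which the phantom
models.  The phantom establishes that the algorithmic machinery behaves
as specified under the statistical structure it assumes, not clinical
performance.

## Validation metrics

Dice = 2TP/(2TP+FP+FN); both-empty masks raise an error rather than
returning a value.  ROC curves use the exhaustive set of distinct U
values as thresholds (ties flip together) and trapezoidal AUC,
equivalent to tie-corrected pairwise concordance; brute-force oracles in
the test suite pin both conventions.  The evaluation mask defaults to
the brain mask — whole-volume true negatives would inflate specificity.
The non-overlap measure is 100·(|A∪B|−|A∩B|)/|A∪B|, a documented
choice of denominator.  The paired Wilcoxon signed-rank test uses the
normal approximation with tie and continuity corrections, z signed so
positive means the first sample is larger; at n = 6 the approximation
agrees with exact sign-assignment enumeration to within 0.05.

## Problem sizes and runtime

All shipped scenarios use the 48³ grid, 12 controls, and 10 replicates
for the paired standard-versus-recursive comparison; the full test
suite runs in well under a minute and `scripts/acceptance.py` in tens
of seconds on a single CPU.  Grid, cohort size and all thresholds are
configurable.
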