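"""Overlap and discrimination metrics for lesion maps.

Dice similarity, ROC/AUC over U thresholds, sensitivity/specificity,
the percentage of non-overlapping voxels between two masks, and a
paired Wilcoxon signed-rank comparison (used to compare AUCs of the
standard and recursive pipelines).  All voxel counting is restricted to
an evaluation mask — by default the brain mask — because whole-volume
true-negative counts over empty background would inflate specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

#: default U threshold sweep for Dice-vs-threshold reporting
DEFAULT_THRESHOLD_SWEEP = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


class DegenerateMasksError(ValueError):
    """A metric is undefined for the given (empty) masks."""


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ROCResult:
    """ROC curve over descending U thresholds plus its AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _as_bool(a) -> np.ndarray:
    return np.asarray(a, dtype=bool)


def confusion(mask, truth, eval_mask=None) -> ConfusionCounts:
    """TP/FP/FN/TN voxel counts of ``mask`` against ``truth`` within ``eval_mask``."""
    mask, truth = _as_bool(mask), _as_bool(truth)
    if mask.shape != truth.shape:
        raise ValueError(f"grid mismatch: {mask.shape} vs {truth.shape}")
    if eval_mask is None:
        eval_mask = np.ones(mask.shape, dtype=bool)
    eval_mask = _as_bool(eval_mask)
    m, t = mask[eval_mask], truth[eval_mask]
    tp = int(np.sum(m & t))
    fp = int(np.sum(m & ~t))
    fn = int(np.sum(~m & t))
    tn = int(np.sum(~m & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def dice(mask, truth, eval_mask=None) -> float:
    """Dice similarity 2·TP / (2·TP + FP + FN); undefined for two empty masks."""
    c = confusion(mask, truth, eval_mask)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise DegenerateMasksError("Dice undefined: both masks empty")
    return 2.0 * c.tp / denom


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)); errors on an empty positive or negative class."""
    if counts.tp + counts.fn == 0:
        raise DegenerateMasksError("sensitivity undefined: no positive voxels")
    if counts.tn + counts.fp == 0:
        raise DegenerateMasksError("specificity undefined: no negative voxels")
    return (
        counts.tp / (counts.tp + counts.fn),
        counts.tn / (counts.tn + counts.fp),
    )


def roc_auc(fuzzy, truth, eval_mask=None, thresholds=None) -> ROCResult:
    """ROC of a fuzzy abnormality map against a binary reference.

    By default every distinct U value within the evaluation mask is a
    threshold (exhaustive sweep; ties flip together), and AUC is the
    trapezoidal area of TPR over FPR — equivalent to tie-corrected
    pairwise concordance.
    """
    u = np.asarray(getattr(fuzzy, "data", fuzzy), dtype=float)
    if hasattr(fuzzy, "u"):  # accept a FuzzyLesionMap directly
        u = np.asarray(fuzzy.u.data, dtype=float)
    truth = _as_bool(truth)
    if eval_mask is None:
        eval_mask = np.ones(truth.shape, dtype=bool)
    eval_mask = _as_bool(eval_mask)
    scores, labels = u[eval_mask].reshape(-1), truth[eval_mask].reshape(-1)
    if labels.all() or not labels.any():
        raise DegenerateMasksError("ROC undefined: truth has a single class")
    if thresholds is None:
        fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
        # roc_curve's leading threshold is inf (the (0,0) anchor)
        auc = float(_skm.auc(fpr, tpr))
        return ROCResult(thr, tpr, fpr, auc)
    thr = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    tpr = np.array([np.mean(scores[labels] > t) for t in thr])
    fpr = np.array([np.mean(scores[~labels] > t) for t in thr])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thr, tpr[1:-1], fpr[1:-1], auc)


def nonoverlap_variability(a, b) -> float:
    """Percent non-overlapping voxels: 100·(|A∪B| − |A∩B|) / |A∪B|."""
    a, b = _as_bool(a), _as_bool(b)
    union = int(np.sum(a | b))
    if union == 0:
        raise DegenerateMasksError("non-overlap undefined: both masks empty")
    inter = int(np.sum(a & b))
    return 100.0 * (union - inter) / union


def paired_signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank z and two-sided p for paired samples.

    Normal approximation with tie correction; zero differences are
    dropped. The z statistic is signed so that positive means x tends
    to exceed y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateMasksError("signed-rank undefined: all differences zero")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    # tie correction to the variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    # continuity correction: W+ moves in discrete steps
    delta = w_plus - mean_w
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var_w) if abs(delta) > 0.5 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def threshold_report(fuzzy, truth, eval_mask=None, thresholds=DEFAULT_THRESHOLD_SWEEP):
    """Per-threshold confusion, Dice, sensitivity and specificity rows.

    Returns a list of dicts (one per threshold) suitable for a CSV
    report; Dice is NaN where undefined.
    """
    u = np.asarray(fuzzy.u.data if hasattr(fuzzy, "u") else fuzzy, dtype=float)
    truth = _as_bool(truth)
    rows = []
    for t in thresholds:
        mask = u > t
        c = confusion(mask, truth, eval_mask)
        try:
            dsc = dice(mask, truth, eval_mask)
        except DegenerateMasksError:
            dsc = float("nan")
        sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else float("nan")
        spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else float("nan")
        rows.append(
            dict(
                threshold=float(t), tp=c.tp, fp=c.fp, fn=c.fn, tn=c.tn,
                dice=dsc, sensitivity=sens, specificity=spec,
            )
        )
    return rows
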