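"""Image-quality and classification metrics.

Image fidelity: PSNR, windowed SSIM (via scikit-image), RMS contrast with
mean normalization, and relative contrast change.  Classification: the
standard confusion-count metrics (accuracy, precision, recall, F1),
ROC/AUC and precision-recall curves (via scikit-learn), and labeled
confusion matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from skimage.metrics import structural_similarity
from sklearn import metrics as _skm

__all__ = [
    "ConfusionCounts",
    "ClassificationMetrics",
    "QualityReport",
    "psnr",
    "ssim",
    "rms_contrast",
    "relative_contrast_change",
    "quality_report",
    "classification_metrics",
    "roc_points",
    "pr_points",
    "confusion_matrix",
]

#: PSNR reported for identical images (MSE = 0).
PSNR_CAP = math.inf


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion tallies; tp+tn+fp+fn = number of scored items."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class ClassificationMetrics(NamedTuple):
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class QualityReport:
    psnr_db: float
    ssim: float
    entropy_before: float
    entropy_after: float
    rms_contrast_before: float
    rms_contrast_after: float
    relative_contrast_change: float


def _check_pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(reference, dtype=float)
    b = np.asarray(test, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(reference: np.ndarray, test: np.ndarray, levels: int = 256) -> float:
    """Peak signal-to-noise ratio, 10*log10((L-1)^2 / MSE) in dB.

    Identical images (MSE = 0) are reported as the infinity sentinel.
    Symmetric in its arguments.
    """
    a, b = _check_pair(reference, test)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP
    return 10.0 * math.log10((levels - 1) ** 2 / mse)


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    window: int = 7,
    stabilizers: tuple[float, float] = (0.01, 0.03),
    levels: int = 256,
) -> float:
    """Mean structural similarity over sliding windows (default 7x7,
    k1=0.01, k2=0.03, data range L-1)."""
    a, b = _check_pair(reference, test)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    k1, k2 = stabilizers
    return float(
        structural_similarity(
            a, b, win_size=window, K1=k1, K2=k2, data_range=float(levels - 1)
        )
    )


def rms_contrast(image: np.ndarray) -> float:
    """Standard deviation of mean-normalized intensities, std(v/mean(v)).

    Mean normalization makes the statistic scale-free; a constant image has
    zero contrast.  A zero-mean image is degenerate and rejected.
    """
    v = np.asarray(image, dtype=float)
    if v.size == 0:
        raise ValueError("empty image")
    mean = float(v.mean())
    if mean == 0.0:
        raise ValueError("zero-mean image: RMS contrast undefined under mean normalization")
    return float(np.std(v / mean))


def relative_contrast_change(before: float, after: float) -> float:
    """(after - before) / before."""
    if before == 0:
        raise ValueError("before-contrast is zero; relative change undefined")
    return (after - before) / before


def quality_report(before: np.ndarray, after: np.ndarray, levels: int = 256) -> QualityReport:
    """Bundle all image-quality metrics for an enhancement before/after pair."""
    from .enhancement import shannon_entropy

    a = np.asarray(before)
    b = np.asarray(after)
    hist_a = np.bincount(a.ravel().astype(np.int64), minlength=levels)[:levels]
    hist_b = np.bincount(b.ravel().astype(np.int64), minlength=levels)[:levels]
    rms_a = rms_contrast(a)
    rms_b = rms_contrast(b)
    return QualityReport(
        psnr_db=psnr(a, b, levels),
        ssim=ssim(a, b, levels=levels),
        entropy_before=shannon_entropy(hist_a),
        entropy_after=shannon_entropy(hist_b),
        rms_contrast_before=rms_a,
        rms_contrast_after=rms_b,
        relative_contrast_change=relative_contrast_change(rms_a, rms_b),
    )


def classification_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy, precision, recall and F1 from confusion counts.

    Undefined ratios (zero denominator) are reported as 0 with a warning.
    """
    total = counts.total
    if total == 0:
        raise ValueError("no scored items")
    accuracy = (counts.tp + counts.tn) / total

    def _safe(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} denominator is zero; reporting 0", stacklevel=3)
            return 0.0
        return num / den

    precision = _safe(counts.tp, counts.tp + counts.fp, "precision")
    recall = _safe(counts.tp, counts.tp + counts.fn, "recall")
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(accuracy, precision, recall, f1)


def roc_points(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve as ordered (FPR, TPR) points (tied scores grouped) and
    trapezoidal AUC.  Requires both classes present."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires at least one positive and one negative label")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    auc = float(_skm.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def pr_points(
    scores: Sequence[float], labels: Sequence[int]
) -> list[tuple[float, float]]:
    """Precision-recall curve as ordered (recall, precision) points."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    precision, recall, _ = _skm.precision_recall_curve(y, s)
    return list(zip(recall.tolist(), precision.tolist()))


def confusion_matrix(
    predictions: Sequence, truths: Sequence, class_order: Sequence
) -> np.ndarray:
    """Confusion matrix with rows = truth, columns = prediction, in the
    given class order; entries sum to the number of items."""
    preds = list(predictions)
    trues = list(truths)
    if len(preds) != len(trues):
        raise ValueError("predictions and truths must have equal length")
    known = set(class_order)
    for lab in preds + trues:
        if lab not in known:
            raise ValueError(f"unknown label: {lab!r}")
    return _skm.confusion_matrix(trues, preds, labels=list(class_order))
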