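"""Pixel-wise validation of predicted Z-disk masks against ground truth.

Pixels are classified exhaustively into TP/TN/FP/FN and summarized as

    accuracy    = (TP + TN) / (TP + TN + FN + FP)
    specificity =  TN / (TN + FP)
    sensitivity =  TP / (TP + FN)

A zero denominator yields ``None`` (explicitly undefined), never a silent
zero.  Counts pool across slices; per-slice reports are kept for diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN pixel tallies between a predicted and a reference mask."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class ValidationReport:
    accuracy: Optional[float]
    specificity: Optional[float]
    sensitivity: Optional[float]
    counts: ConfusionCounts
    per_slice: Optional[List["ValidationReport"]] = None

    def as_percentages(self) -> dict:
        return {
            name: (None if value is None else 100.0 * value)
            for name, value in (("accuracy", self.accuracy),
                                ("specificity", self.specificity),
                                ("sensitivity", self.sensitivity))
        }


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Classify every pixel of ``pred`` against ``truth``.

    Masks may be boolean or 0/255 rasters; any nonzero value is foreground.
    """
    pred = np.asarray(pred) != 0
    truth = np.asarray(truth) != 0
    if pred.shape != truth.shape:
        raise ValueError(
            f"footprint mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts) -> ValidationReport:
    """Accuracy, specificity and sensitivity from a set of pixel tallies."""
    if counts.total == 0:
        raise ValueError("all four counts are zero; nothing to evaluate")
    return ValidationReport(
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        counts=counts,
    )


def evaluate_masks(preds: Sequence[np.ndarray], truths: Sequence[np.ndarray],
                   boundary_tolerance: bool = False) -> ValidationReport:
    """Pooled validation of a stack of predictions against annotations.

    Pooled counts (the headline numbers) are the sums of the per-slice
    counts, which are kept on the report for diagnosis.  With
    ``boundary_tolerance`` the truth is dilated by one pixel before
    matching; strict pixel matching is the default.
    """
    if len(preds) != len(truths):
        raise ValueError("need one truth mask per predicted mask")
    if len(preds) == 0:
        raise ValueError("no masks to evaluate")
    per_slice: List[ValidationReport] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for pred, truth in zip(preds, truths):
        if boundary_tolerance:
            from scipy import ndimage
            truth = ndimage.binary_dilation(np.asarray(truth) != 0,
                                            structure=np.ones((3, 3), bool))
        counts = confusion_counts(pred, truth)
        per_slice.append(compute_metrics(counts))
        pooled = pooled + counts
    headline = compute_metrics(pooled)
    return ValidationReport(accuracy=headline.accuracy,
                            specificity=headline.specificity,
                            sensitivity=headline.sensitivity,
                            counts=pooled, per_slice=per_slice)
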