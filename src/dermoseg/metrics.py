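"""Pixel-level evaluation of predicted lesion masks against ground truth.

The headline metric is pixel accuracy, (TP + TN) / (TP + FP + TN + FN),
reported per image and as an unweighted mean over a dataset (per-image
averaging, the common convention for segmentation benchmarks). Dice,
Jaccard, sensitivity and specificity are reported alongside.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .segmentation import SegmentationConfig, segment

__all__ = [
    "ConfusionCounts",
    "ImageResult",
    "EvaluationReport",
    "confusion_counts",
    "accuracy",
    "dice",
    "jaccard",
    "sensitivity",
    "specificity",
    "evaluate_dataset",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """Pixel confusion counts between a predicted and a true binary mask."""
    pred = np.asarray(predicted) > 0
    true = np.asarray(truth) > 0
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + TN + FN)."""
    if counts.total == 0:
        raise ValueError("accuracy undefined for empty masks (zero total count)")
    return (counts.tp + counts.tn) / counts.total


def dice(counts: ConfusionCounts) -> float:
    denom = 2 * counts.tp + counts.fp + counts.fn
    return 2 * counts.tp / denom if denom else math.nan


def jaccard(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp + counts.fn
    return counts.tp / denom if denom else math.nan


def sensitivity(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else math.nan


def specificity(counts: ConfusionCounts) -> float:
    denom = counts.tn + counts.fp
    return counts.tn / denom if denom else math.nan


@dataclasses.dataclass(frozen=True)
class ImageResult:
    identifier: str
    counts: ConfusionCounts
    accuracy: float
    dice: float
    jaccard: float
    sensitivity: float
    specificity: float


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    per_image: tuple
    skipped: tuple  # (identifier, reason) pairs

    @property
    def n_images(self) -> int:
        return len(self.per_image)

    @property
    def mean_accuracy(self) -> float:
        if not self.per_image:
            return math.nan
        return float(np.mean([r.accuracy for r in self.per_image]))

    @property
    def mean_dice(self) -> float:
        if not self.per_image:
            return math.nan
        return float(np.mean([r.dice for r in self.per_image]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "identifier": r.identifier,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "tn": r.counts.tn,
                "fn": r.counts.fn,
                "accuracy": r.accuracy,
                "dice": r.dice,
                "jaccard": r.jaccard,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
            for r in self.per_image
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n_images": self.n_images,
            "n_skipped": len(self.skipped),
            "skipped": [{"identifier": i, "reason": r} for i, r in self.skipped],
            "mean_accuracy": self.mean_accuracy,
            "mean_dice": self.mean_dice,
        }


def _score(predicted, truth, identifier: str) -> ImageResult:
    counts = confusion_counts(predicted, truth)
    return ImageResult(
        identifier=identifier,
        counts=counts,
        accuracy=accuracy(counts),
        dice=dice(counts),
        jaccard=jaccard(counts),
        sensitivity=sensitivity(counts),
        specificity=specificity(counts),
    )


def evaluate_dataset(
    pairs: Iterable,
    config: SegmentationConfig | None = None,
) -> EvaluationReport:
    """Segment every (image, truth_mask, identifier) triple and score it.

    Failing images (decoding problems, shape mismatches) are skipped and
    recorded in the report rather than aborting the run. An empty input
    sequence is an error.
    """
    results = []
    skipped = []
    n_seen = 0
    for image, truth, identifier in pairs:
        n_seen += 1
        try:
            res = segment(image, config)
            results.append(_score(res.mask, truth, str(identifier)))
        except Exception as exc:  # per-image failure: record and continue
            skipped.append((str(identifier), str(exc)))
    if n_seen == 0:
        raise ValueError("evaluate_dataset received no image/mask pairs")
    return EvaluationReport(per_image=tuple(results), skipped=tuple(skipped))
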