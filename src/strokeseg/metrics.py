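"""Evaluation metrics: confusion counts, Dice coefficient, accuracy.

Dice = 2TP / (2TP + FP + FN); accuracy = (TP + TN) / (TP + TN + FP + FN).
Both derive from exact integer confusion counts of binary masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "dice_coefficient", "accuracy",
           "dice_from_masks", "accuracy_from_masks"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return a.astype(bool)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact pixel confusion counts between two binary masks."""
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    tp = int(np.sum(yt & yp))
    tn = int(np.sum(~yt & ~yp))
    fp = int(np.sum(~yt & yp))
    fn = int(np.sum(yt & ~yp))
    return ConfusionCounts(tp, tn, fp, fn)


def dice_coefficient(counts: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN); defined as 1.0 when both masks are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2.0 * counts.tp / denom


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / M over all M pixels."""
    if counts.total == 0:
        raise ValueError("accuracy undefined for zero pixels")
    return (counts.tp + counts.tn) / counts.total


def dice_from_masks(y_true, y_pred) -> float:
    return dice_coefficient(confusion(y_true, y_pred))


def accuracy_from_masks(y_true, y_pred) -> float:
    return accuracy(confusion(y_true, y_pred))
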