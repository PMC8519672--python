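"""Evaluation indices: confusion counts, accuracy, Dice coefficient, and
per-volume / pooled aggregation over prediction-truth directory pairs.

Pooled metrics sum confusion counts across volumes *before* dividing, which
in general differs from averaging per-volume scores; both are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "accuracy",
    "dice_coefficient",
    "evaluate_volumes",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Voxelwise 2x2 tally of a binary prediction against binary truth."""
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    for name, arr in (("pred", p), ("truth", t)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary {{0,1}}")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN) / total: the proportion of correctly labelled voxels."""
    if c.total == 0:
        raise ValueError("accuracy undefined for zero total count")
    return (c.tp + c.tn) / c.total


def dice_coefficient(c: ConfusionCounts) -> float:
    """2·TP / (2·TP + FP + FN), in [0, 1].

    When both regions are empty (denominator 0) the overlap is perfect by
    convention and 1.0 is returned, with a logged note.
    """
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        logger.info("dice_coefficient: both regions empty; returning 1.0 by convention")
        return 1.0
    return 2 * c.tp / denom


def evaluate_volumes(pred_dir, truth_dir) -> pd.DataFrame:
    """Per-volume and pooled metrics for LiTS-style segmentation directories.

    Both directories must contain matching ``segmentation-i.nii`` files.
    Returns a DataFrame with one row per volume plus a final ``pooled`` row
    whose counts are summed before computing accuracy and Dice.
    """
    from pathlib import Path

    from . import data_io

    def _masks(directory):
        directory = Path(directory)
        found = {}
        for p in sorted(directory.glob("segmentation-*.nii*")):
            idx = int(p.name.split("-")[1].split(".")[0])
            found[idx] = p
        return found

    preds, truths = _masks(pred_dir), _masks(truth_dir)
    unpaired = sorted(set(preds) ^ set(truths))
    if unpaired:
        raise ValueError(f"unpaired case indices between directories: {unpaired}")
    if not preds:
        raise ValueError("no segmentation-*.nii files found")

    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for idx in sorted(preds):
        p = (data_io.read_nifti_volume(preds[idx]).voxels >= 0.5).astype(np.uint8)
        t = (data_io.read_nifti_volume(truths[idx]).voxels >= 0.5).astype(np.uint8)
        c = confusion_counts(p, t)
        pooled = pooled + c
        rows.append({"case": str(idx), "tp": c.tp, "fp": c.fp, "fn": c.fn,
                     "tn": c.tn, "accuracy": accuracy(c),
                     "dice": dice_coefficient(c)})
    rows.append({"case": "pooled", "tp": pooled.tp, "fp": pooled.fp,
                 "fn": pooled.fn, "tn": pooled.tn,
                 "accuracy": accuracy(pooled),
                 "dice": dice_coefficient(pooled)})
    return pd.DataFrame(rows)
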