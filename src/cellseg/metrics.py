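"""Evaluation metrics from pixel confusion counts.

All four metrics are reported as percentages of the standard ratios

    Dice      = 2TP / (2TP + FP + FN)
    MIoU      = TP / (TP + FP + FN)        (single-class foreground IoU)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)

Note the IoU here is the single-foreground-class ratio, not an average
over classes, matching how segmentation of a single cell class is scored.
Conventions for degenerate inputs: when both masks are empty the overlap
metrics are perfect (100); a zero precision/recall denominator yields NaN,
which callers exclude from averages.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "dice_score",
    "miou",
    "precision",
    "recall",
    "metrics_row",
    "write_metrics_csv",
]

METRIC_COLUMNS = ("dice_pct", "miou_pct", "precision_pct", "recall_pct")


@dataclass
class ConfusionCounts:
    """Pixel tallies; TP+FP+FN+TN equals the number of evaluated pixels."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN between two binary masks of identical shape."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    for name, m in (("pred_mask", pred), ("true_mask", true)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    pred = pred.astype(bool)
    true = true.astype(bool)
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    return ConfusionCounts(tp, fp, fn, pred.size - tp - fp - fn)


def dice_score(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 100.0  # both masks empty: perfect agreement by convention
    return 100.0 * 2 * c.tp / denom


def miou(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 100.0
    return 100.0 * c.tp / denom


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    if denom == 0:
        return float("nan")  # nothing predicted positive: undefined
    return 100.0 * c.tp / denom


def recall(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    if denom == 0:
        return float("nan")  # no positives present: undefined
    return 100.0 * c.tp / denom


def metrics_row(c: ConfusionCounts) -> dict[str, float]:
    """The four metrics as a dict keyed by the CSV column names."""
    return {
        "dice_pct": dice_score(c),
        "miou_pct": miou(c),
        "precision_pct": precision(c),
        "recall_pct": recall(c),
    }


def write_metrics_csv(rows: list[dict], path: str | Path) -> Path:
    """Rows of {variant, dice_pct, miou_pct, precision_pct, recall_pct}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=("variant",) + METRIC_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in ("variant",) + METRIC_COLUMNS})
    return path
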