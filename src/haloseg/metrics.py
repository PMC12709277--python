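"""Pixelwise segmentation metrics and confluency estimation.

All evaluation is pixel-level against a reference binary mask: the confusion
counts (TP, FP, FN, TN) yield accuracy, recall, precision and F1, and the
predicted-foreground area fraction is the cell confluency

    confluency = (TP + FP) / (TP + FP + TN + FN),

whose headline error against a staining-derived "standard" confluency is the
absolute difference of the two fractions (the signed difference is retained
for diagnostics).  Ratios with zero denominator are reported as undefined
(``None``), distinct from 0, and excluded from aggregate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "SegmentationMetrics",
    "ConfluencyResult",
    "confusion_counts",
    "compute_metrics",
    "compute_confluency",
    "confluency_error",
    "evaluate_batch",
]


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
class SegmentationMetrics:
    """Accuracy/recall/precision/F1 as fractions in [0, 1]; None = undefined."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    f1: float | None


@dataclass
class ConfluencyResult:
    confluency: float
    standard_confluency: float | None = None
    error: float | None = None  # |method - standard|
    signed_error: float | None = None  # method - standard


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion tally between a predicted and a reference mask."""
    p = np.asarray(pred) > 0
    t = np.asarray(truth) > 0
    if p.shape != t.shape:
        raise ValueError(f"mask dimension mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts) -> SegmentationMetrics:
    """Accuracy, recall, precision and F1 from confusion counts."""
    if counts.total <= 0:
        raise ValueError("confusion counts are empty")
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None if (precision is None or recall is None) else 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return SegmentationMetrics(
        accuracy=(counts.tp + counts.tn) / counts.total,
        recall=recall,
        precision=precision,
        f1=f1,
    )


def compute_confluency(mask: np.ndarray) -> float:
    """Foreground area fraction of a mask."""
    m = np.asarray(mask)
    if m.size == 0:
        raise ValueError("mask is empty")
    return float(np.count_nonzero(m > 0) / m.size)


def confluency_error(method: float, standard: float) -> float:
    """Absolute confluency error |method - standard| between two fractions."""
    for name, value in (("method", method), ("standard", standard)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} confluency {value} outside [0, 1]")
    return abs(method - standard)


def evaluate_batch(
    pred_masks,
    truth_masks,
    standards=None,
    image_ids=None,
) -> tuple[pd.DataFrame, dict]:
    """Per-image metrics table plus unweighted means.

    Returns a DataFrame with one row per image (confusion counts, metrics,
    confluency and — when ``standards`` is given — the confluency error) and
    a summary dict with per-metric means over the defined values, the count
    of undefined entries, and pooled-pixel metrics computed from the summed
    confusion counts.
    """
    preds = list(pred_masks)
    truths = list(truth_masks)
    if len(preds) != len(truths):
        raise ValueError("pred/truth list length mismatch")
    if standards is not None and len(list(standards)) != len(preds):
        raise ValueError("standards length mismatch")
    if image_ids is None:
        image_ids = [f"image_{i:03d}" for i in range(len(preds))]

    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for i, (p, t) in enumerate(zip(preds, truths)):
        counts = confusion_counts(p, t)
        pooled.tp += counts.tp
        pooled.fp += counts.fp
        pooled.fn += counts.fn
        pooled.tn += counts.tn
        m = compute_metrics(counts)
        conf = compute_confluency(p)
        row = {
            "image_id": image_ids[i],
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "tn": counts.tn,
            "accuracy": m.accuracy,
            "recall": m.recall,
            "precision": m.precision,
            "f1": m.f1,
            "confluency": conf,
            "standard_confluency": None,
            "error": None,
        }
        if standards is not None:
            std = list(standards)[i]
            if std is not None:
                row["standard_confluency"] = float(std)
                row["error"] = confluency_error(conf, float(std))
        rows.append(row)

    table = pd.DataFrame(rows)
    summary: dict = {"n_images": len(rows), "undefined": {}}
    for col in ("accuracy", "recall", "precision", "f1", "confluency", "error"):
        values = table[col].dropna()
        summary[f"mean_{col}"] = float(values.mean()) if len(values) else None
        summary["undefined"][col] = int(table[col].isna().sum())
    pm = compute_metrics(pooled) if pooled.total else None
    summary["pooled"] = (
        {
            "accuracy": pm.accuracy,
            "recall": pm.recall,
            "precision": pm.precision,
            "f1": pm.f1,
        }
        if pm
        else None
    )
    return table, summary
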