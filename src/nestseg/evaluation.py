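"""Pixelwise segmentation metrics.

The positive class is "nest".  The Dice similarity coefficient is exposed in
both its set form 2|X∩Y|/(|X|+|Y|) and its confusion-count form
2TP/(2TP+FP+FN); the two are algebraically identical, which the test suite
checks on random masks.  When both the prediction and the reference are
empty, DSC is defined as 1.0 (the standard convention; the expression is
otherwise 0/0).  Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) default
to 1.0 with a warning when their denominator is zero.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np

from .inference import predict_mask
from .model import ContractError
from .patching import DataError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegMetrics:
    dsc: float
    sensitivity: float
    specificity: float


def _as_binary(mask) -> np.ndarray:
    arr = mask.values if hasattr(mask, "values") else np.asarray(mask)
    return arr.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN counts for binary masks of equal shape."""
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ContractError(f"shape mismatch {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(counts: ConfusionCounts) -> float:
    """Dice similarity 2TP/(2TP+FP+FN); 1.0 when both masks are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2.0 * counts.tp / denom


def dsc_sets(x, y) -> float:
    """Set form 2|X∩Y|/(|X|+|Y|) evaluated directly on the masks."""
    xb, yb = _as_binary(x), _as_binary(y)
    if xb.shape != yb.shape:
        raise ContractError("shape mismatch")
    size_sum = int(xb.sum()) + int(yb.sum())
    if size_sum == 0:
        return 1.0
    return 2.0 * int((xb & yb).sum()) / size_sum


def sensitivity(counts: ConfusionCounts) -> float:
    """TP/(TP+FN); 1.0 (with a warning) when no positive reference pixels."""
    if counts.tp + counts.fn == 0:
        warnings.warn("sensitivity undefined (no positive pixels); using 1.0")
        return 1.0
    return counts.tp / (counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    """TN/(TN+FP); 1.0 (with a warning) when no negative reference pixels."""
    if counts.tn + counts.fp == 0:
        warnings.warn("specificity undefined (no negative pixels); using 1.0")
        return 1.0
    return counts.tn / (counts.tn + counts.fp)


def metrics_from_counts(counts: ConfusionCounts) -> SegMetrics:
    return SegMetrics(dsc(counts), sensitivity(counts), specificity(counts))


def evaluate_corpus(model, images, stride: int = 128, threshold: float = 0.5,
                    pooled: bool = False, report_path=None):
    """Per-image metrics via whole-image prediction, plus their average.

    Returns ``(per_image, summary)`` where ``per_image`` maps image_id to
    (ConfusionCounts, SegMetrics) and ``summary`` is the unweighted
    per-image mean of each metric (the default), or metrics of the pooled
    pixel counts when ``pooled``.
    """
    labeled = [s for s in images if s.mask is not None]
    if not labeled:
        raise DataError("evaluation requires at least one labeled image")
    per_image: dict[str, tuple[ConfusionCounts, SegMetrics]] = {}
    for slide in labeled:
        mask, _ = predict_mask(model, slide, stride=stride, threshold=threshold)
        counts = confusion(mask.values, slide.mask)
        per_image[slide.image_id] = (counts, metrics_from_counts(counts))
    if pooled:
        agg = ConfusionCounts(*(sum(getattr(c, k) for c, _ in per_image.values())
                                for k in ("tp", "fp", "fn", "tn")))
        summary = metrics_from_counts(agg)
    else:
        summary = SegMetrics(
            float(np.mean([m.dsc for _, m in per_image.values()])),
            float(np.mean([m.sensitivity for _, m in per_image.values()])),
            float(np.mean([m.specificity for _, m in per_image.values()])),
        )
    if report_path is not None:
        with open(report_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image_id", "tp", "fp", "fn", "tn",
                        "dsc", "sensitivity", "specificity"])
            for image_id, (c, m) in per_image.items():
                w.writerow([image_id, c.tp, c.fp, c.fn, c.tn,
                            f"{m.dsc:.6f}", f"{m.sensitivity:.6f}",
                            f"{m.specificity:.6f}"])
            w.writerow(["average", "", "", "", "", f"{summary.dsc:.6f}",
                        f"{summary.sensitivity:.6f}",
                        f"{summary.specificity:.6f}"])
    return per_image, summary
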