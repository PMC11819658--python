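"""Detection-map post-processing and pixel-level accuracy metrics.

Per-channel probability vectors are thresholded to binary vectors, reshaped
to the source image, denoised with a k×k median filter (on binary maps the
median is the neighbourhood majority), and fused across the two tissue
channels — pixel-wise AND by default, so a pixel is called foreign material
only when both channels agree. Accuracy is reported as precision, recall,
F1 (computed without the true negatives), balanced accuracy and overall
accuracy over an optional evaluation mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class DetectionMap:
    """Binary H×W foreign-material map plus the settings that produced it."""

    map: np.ndarray
    channel: str = "fused"  # muscle | nonmuscle | fused
    threshold: float = 0.5
    filter_kernel: int = 3

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map)
        if not np.isin(self.map, (0, 1)).all():
            raise ValueError("detection map must be binary")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricsRecord:
    precision: float
    recall: float
    f1: float
    bacc: float
    acc: float


def threshold_probs(probabilities: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Binary decision per pixel: 1 where p >= t."""
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    p = np.asarray(probabilities)
    return (p >= t).astype(np.uint8)


def median_filter(binary_map: np.ndarray, k: int = 3) -> np.ndarray:
    """k×k median (majority) filter with reflect padding; k odd."""
    if k < 1 or k % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    m = np.asarray(binary_map)
    if k == 1:
        return m.astype(np.uint8)
    return ndimage.median_filter(m.astype(np.uint8), size=k, mode="reflect")


def fuse_maps(
    map_muscle: np.ndarray,
    map_nonmuscle: np.ndarray,
    rule: str = "and",
    threshold: float = 0.5,
    filter_kernel: int = 3,
) -> DetectionMap:
    """Combine the two channel maps into the final pixel-level FM map.

    The default intersection rule trades recall for precision: a
    false positive raised by a single channel is suppressed unless the other
    channel agrees. An OR rule is available for recall-critical settings.
    """
    a = np.asarray(map_muscle)
    b = np.asarray(map_nonmuscle)
    if a.shape != b.shape:
        raise ValueError("channel maps must share a shape")
    if rule == "and":
        fused = (a.astype(bool) & b.astype(bool)).astype(np.uint8)
    elif rule == "or":
        fused = (a.astype(bool) | b.astype(bool)).astype(np.uint8)
    else:
        raise ValueError(f"unknown fusion rule {rule!r}")
    return DetectionMap(
        map=fused, channel="fused", threshold=threshold, filter_kernel=filter_kernel
    )


def confusion(pred, truth, eval_mask: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel confusion counts of a binary prediction against binary truth,
    restricted to ``eval_mask`` when given (default: every pixel)."""
    p = np.asarray(getattr(pred, "map", pred)).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must share a shape")
    if eval_mask is None:
        mask = np.ones_like(t, dtype=bool)
    else:
        mask = np.asarray(eval_mask).astype(bool)
        if mask.shape != t.shape:
            raise ValueError("eval_mask must share the truth shape")
    p, t = p[mask], t[mask]
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
        TN=int(np.sum(~p & ~t)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsRecord:
    """Precision, recall, F1 (TN-free), balanced accuracy, overall accuracy.

    Undefined ratios (e.g. precision with no positive predictions) are
    reported as NaN with a warning rather than silently as zero.
    """
    if counts.total == 0:
        raise ValueError("confusion counts are all zero")
    precision = _ratio(counts.TP, counts.TP + counts.FP, "precision")
    recall = _ratio(counts.TP, counts.TP + counts.FN, "recall")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan") if np.isnan(precision) or np.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    tnr = _ratio(counts.TN, counts.TN + counts.FP, "specificity")
    bacc = (recall + tnr) / 2.0
    acc = (counts.TP + counts.TN) / counts.total
    return MetricsRecord(precision=precision, recall=recall, f1=f1, bacc=bacc, acc=acc)
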