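"""Segmentation evaluation: confusion counts and the metric suite.

Undefined ratios (zero denominators) are reported as NaN with a warning,
never silently as 0; the one documented exception is MCC, which returns
0 when any confusion-matrix marginal is empty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidImageError, UndefinedMetricWarning

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "precision_recall",
    "accuracy",
    "adaptive_threshold",
    "f_measure",
    "mcc",
    "jaccard",
    "dice",
    "specificity",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _undefined(name: str) -> float:
    warnings.warn(f"{name} undefined (zero denominator)", UndefinedMetricWarning, stacklevel=3)
    return float("nan")


def confusion(pred: np.ndarray, gt: np.ndarray, positive: int = 1) -> ConfusionCounts:
    """Standard confusion counts between two same-shape binary masks.

    ``positive`` selects the polarity of the positive class (default 1);
    pass 0 to score the complementary class instead.
    """
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise InvalidImageError(f"shape mismatch: {p.shape} vs {g.shape}")
    if positive == 0:
        p, g = ~p, ~g
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        tn=int(np.sum(~p & ~g)),
        fn=int(np.sum(~p & g)),
    )


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else _undefined("precision")
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else _undefined("recall")
    return precision, recall


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else _undefined("accuracy")


def adaptive_threshold(arr: np.ndarray) -> float:
    """Twice the mean of a sharpness/edge map."""
    return 2.0 * float(np.mean(arr))


def f_measure(precision: float, recall: float, kappa_sq: float = 0.3) -> float:
    """Weighted F-measure (1 + k^2) P R / (k^2 P + R)."""
    denom = kappa_sq * precision + recall
    if denom == 0 or not np.isfinite(denom):
        return _undefined("f_measure")
    return (1.0 + kappa_sq) * precision * recall / denom


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 on a zero marginal."""
    denom2 = (
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom2 == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom2)


def jaccard(u: np.ndarray, v: np.ndarray) -> float:
    """Weighted Jaccard sum(min)/sum(max); 1 when both inputs are empty."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise InvalidImageError(f"shape mismatch: {u.shape} vs {v.shape}")
    denom = float(np.sum(np.maximum(u, v)))
    if denom == 0:
        return 1.0
    return float(np.sum(np.minimum(u, v))) / denom


def dice(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else _undefined("dice")


def specificity(c: ConfusionCounts) -> float:
    denom = c.tn + c.fp
    return c.tn / denom if denom else _undefined("specificity")


@dataclass
class MetricsReport:
    precision: float
    recall: float
    accuracy: float
    f_kappa: float
    mcc: float
    jaccard: float
    dice: float
    specificity: float
    kappa_sq: float = 0.3

    @classmethod
    def from_masks(cls, pred, gt, positive: int = 1, kappa_sq: float = 0.3) -> "MetricsReport":
        c = confusion(pred, gt, positive=positive)
        p, r = precision_recall(c)
        pm = np.asarray(pred).astype(bool)
        gm = np.asarray(gt).astype(bool)
        if positive == 0:
            pm, gm = ~pm, ~gm
        return cls(
            precision=p,
            recall=r,
            accuracy=accuracy(c),
            f_kappa=f_measure(p, r, kappa_sq),
            mcc=mcc(c),
            jaccard=jaccard(pm, gm),
            dice=dice(c),
            specificity=specificity(c),
            kappa_sq=kappa_sq,
        )

    def to_dict(self) -> dict:
        return asdict(self)
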