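"""Label smoothing, smoothed cross-entropy losses, confusion counts and
the four evaluation metrics (accuracy, precision, recall, F1).

Smoothing replaces hard targets with y' = (1 - v) * y + v/K (error rate
v, K classes), which keeps one-hot targets summing to 1 and regularizes
the loss.  Two losses operate on smoothed targets:

* ``smoothed_categorical_loss``: -sum_k y'_k log(p_k), the softmax-head
  cross entropy ("lg" taken as the natural log; the base is configurable
  and only rescales the value);
* ``smoothed_binary_loss``: per-class binary cross entropy
  -sum_k [y'_k log p_k + (1 - y'_k) log(1 - p_k)], the right objective
  for the independent multi-label sigmoid head.

Metrics follow the per-class confusion-count definitions
A = (TP+TN)/(TP+FP+TN+FN), P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2TP/(2TP+FP+FN); micro pools counts over classes, macro averages
the per-class values.  Zero denominators yield 0 with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CLASSES

logger = logging.getLogger(__name__)

PROB_EPS = 1e-7  # clamp for log arguments


@dataclass
class SmoothingParams:
    v: float = 0.1
    K: int = 8

    def validate(self):
        if not (0.0 <= self.v < 1.0):
            raise ValueError("smoothing error rate v must lie in [0, 1)")
        if self.K < 1:
            raise ValueError("K must be a positive class count")


def smooth_labels(y, params: SmoothingParams | None = None) -> np.ndarray:
    """y'_k = (1 - v) * y_k + v / K, elementwise."""
    params = params or SmoothingParams()
    params.validate()
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != params.K:
        raise ValueError(f"expected {params.K} classes, got {y.shape[-1]}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be multi-hot 0/1 before smoothing")
    return (1.0 - params.v) * y + params.v / params.K


def smoothed_categorical_loss(y_smooth, y_hat, base: str = "natural") -> float:
    """-sum_k y'_k log(p_k); log base natural by default, "10" selectable."""
    y_smooth = np.asarray(y_smooth, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_smooth.shape != y_hat.shape:
        raise ValueError("smoothed labels and predictions must share shape")
    p = np.clip(y_hat, PROB_EPS, 1.0)
    logs = np.log(p) if base == "natural" else np.log10(p)
    return float(-(y_smooth * logs).sum(axis=-1).mean())


# the spec's single-loss surface name
smoothed_loss = smoothed_categorical_loss


def smoothed_binary_loss(y_smooth, y_hat) -> float:
    """Per-class binary cross entropy on smoothed targets, summed over
    classes and averaged over samples."""
    y_smooth = np.asarray(y_smooth, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_smooth.shape != y_hat.shape:
        raise ValueError("smoothed labels and predictions must share shape")
    p = np.clip(y_hat, PROB_EPS, 1.0 - PROB_EPS)
    terms = y_smooth * np.log(p) + (1.0 - y_smooth) * np.log(1.0 - p)
    return float(-terms.sum(axis=-1).mean())


# ---------------------------------------------------------------------------
# confusion counts and metrics


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/TN/FN arrays (one entry per class, fixed order)."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        totals = self.tp + self.fp + self.tn + self.fn
        if len(set(totals.tolist())) > 1:
            raise ValueError("per-class totals must agree (one per evaluated sample)")

    @property
    def n_samples(self) -> int:
        return int((self.tp + self.fp + self.tn + self.fn)[0]) if self.tp.size else 0

    def pooled(self) -> "ConfusionCounts":
        return ConfusionCounts(self.tp.sum(keepdims=True), self.fp.sum(keepdims=True),
                               self.tn.sum(keepdims=True), self.fn.sum(keepdims=True))


def confusion(y_true, y_prob, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold probabilities (p >= threshold) and count per class."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must share shape")
    if not np.isin(y_true, (0, 1)).all():
        raise ValueError("y_true must be multi-hot 0/1")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    pred = y_prob >= threshold
    truth = y_true.astype(bool)
    return ConfusionCounts(
        tp=(pred & truth).sum(axis=0), fp=(pred & ~truth).sum(axis=0),
        tn=(~pred & ~truth).sum(axis=0), fn=(~pred & truth).sum(axis=0))


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    zero = den == 0
    if zero.any():
        logger.warning("zero denominator in metric computation; reporting 0")
    np.divide(num, den, out=out, where=~zero)
    return out


def _four(tp, fp, tn, fn):
    return {
        "accuracy": _safe_div(tp + tn, tp + fp + tn + fn),
        "precision": _safe_div(tp, tp + fp),
        "recall": _safe_div(tp, tp + fn),
        "f1": _safe_div(2 * tp, 2 * tp + fp + fn),
    }


def metrics(counts: ConfusionCounts, averaging: str = "per_class"):
    """Accuracy/precision/recall/F1 from confusion counts.

    ``per_class`` returns arrays (one value per class); ``micro`` pools
    the counts first; ``macro`` averages the per-class values.
    """
    if averaging == "per_class":
        return _four(counts.tp, counts.fp, counts.tn, counts.fn)
    if averaging == "micro":
        p = counts.pooled()
        return {k: float(v[0]) for k, v in
                _four(p.tp, p.fp, p.tn, p.fn).items()}
    if averaging == "macro":
        per = _four(counts.tp, counts.fp, counts.tn, counts.fn)
        return {k: float(v.mean()) for k, v in per.items()}
    raise ValueError(f"unknown averaging mode {averaging!r}")


def metrics_report(counts: ConfusionCounts) -> pd.DataFrame:
    """Per-class table plus micro/macro summary rows, ready for CSV."""
    per = metrics(counts, "per_class")
    rows = []
    for i, cls in enumerate(CLASSES):
        rows.append({"class": cls, "TP": int(counts.tp[i]), "FP": int(counts.fp[i]),
                     "TN": int(counts.tn[i]), "FN": int(counts.fn[i]),
                     **{k: float(v[i]) for k, v in per.items()}})
    pooled = counts.pooled()
    rows.append({"class": "micro", "TP": int(pooled.tp[0]), "FP": int(pooled.fp[0]),
                 "TN": int(pooled.tn[0]), "FN": int(pooled.fn[0]),
                 **metrics(counts, "micro")})
    rows.append({"class": "macro", "TP": math.nan, "FP": math.nan,
                 "TN": math.nan, "FN": math.nan, **metrics(counts, "macro")})
    return pd.DataFrame(rows)
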