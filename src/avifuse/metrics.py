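"""Multi-class evaluation: accuracy, precision, recall, F1 and average
confidence score (ACS), from a confusion matrix with one-vs-rest class counts.

Precision/recall aggregate per-class one-vs-rest values either macro
(unweighted mean; the default) or weighted (support-weighted mean).  The
report-level F1 is the harmonic mean of the aggregated precision and recall.
ACS is the mean probability assigned to the predicted class — a calibration
style summary of how certain the classifier is about its own outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import LabelVocabulary

__all__ = [
    "ConfusionMatrix",
    "ClassCounts",
    "MetricReport",
    "confusion_matrix",
    "class_counts",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "acs",
    "metric_report",
]

_MODES = ("macro", "weighted")


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    vocabulary: LabelVocabulary

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {c.shape}")
        if c.shape[0] != len(self.vocabulary):
            raise ValueError("matrix size does not match vocabulary")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("confusion matrix entries must be non-negative integers")
        object.__setattr__(self, "counts", c)

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        cls = list(self.vocabulary)
        return pd.DataFrame(self.counts, index=cls, columns=cls)


@dataclass(frozen=True)
class ClassCounts:
    """Per-class one-vs-rest TP/TN/FP/FN (each array of length K)."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray


def confusion_matrix(true_labels: Sequence[str], predicted_labels: Sequence[str],
                     vocabulary: LabelVocabulary) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a K x K matrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label lists differ in length")
    k = len(vocabulary)
    idx = {c: i for i, c in enumerate(vocabulary)}
    counts = np.zeros((k, k), dtype=int)
    for s, (t, p) in enumerate(zip(true_labels, predicted_labels)):
        if t not in idx:
            raise ValueError(f"sample {s}: unknown true label {t!r}")
        if p not in idx:
            raise ValueError(f"sample {s}: unknown predicted label {p!r}")
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts, vocabulary)


def class_counts(cm: ConfusionMatrix) -> ClassCounts:
    """One-vs-rest TP/TN/FP/FN per class; each quadruple sums to N."""
    c = cm.counts
    tp = np.diag(c).astype(int)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    tn = c.sum() - tp - fp - fn
    return ClassCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples (trace / N)."""
    n = cm.n_samples
    if n == 0:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return float(np.trace(cm.counts)) / n


def _aggregate(per_class: np.ndarray, support: np.ndarray, mode: str) -> float:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if mode == "macro":
        return float(per_class.mean())
    total = support.sum()
    if total == 0:
        return 0.0
    return float((per_class * support).sum() / total)


def _per_class_ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """num/den per class; zero-denominator classes get 0 and are flagged."""
    zero = den == 0
    out = np.zeros(len(num), dtype=float)
    np.divide(num, den, out=out, where=~zero)
    return out, zero


def precision(cm: ConfusionMatrix, mode: str = "macro") -> float:
    """Aggregated one-vs-rest precision TP / (TP + FP)."""
    cc = class_counts(cm)
    per_class, _ = _per_class_ratio(cc.tp, cc.tp + cc.fp)
    return _aggregate(per_class, cc.tp + cc.fn, mode)


def recall(cm: ConfusionMatrix, mode: str = "macro") -> float:
    """Aggregated one-vs-rest recall TP / (TP + FN)."""
    cc = class_counts(cm)
    per_class, _ = _per_class_ratio(cc.tp, cc.tp + cc.fn)
    return _aggregate(per_class, cc.tp + cc.fn, mode)


def f1(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if p < 0 or r < 0:
        raise ValueError("precision and recall must be non-negative")
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def acs(confidences: Sequence[float]) -> float:
    """Average confidence score: mean top-class probability over samples."""
    c = np.asarray(confidences, dtype=float)
    if c.size == 0:
        raise ValueError("ACS of an empty confidence list is undefined")
    if np.any(c <= 0) or np.any(c > 1):
        raise ValueError("confidences must lie in (0, 1]")
    return float(c.mean())


@dataclass(frozen=True)
class MetricReport:
    """A/P/R/FS/ACS on [0, 1] plus the per-class table and confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    acs: float
    mode: str
    per_class: pd.DataFrame
    cm: ConfusionMatrix
    zero_denominator_classes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "metrics": {"A": self.accuracy, "P": self.precision, "R": self.recall,
                        "FS": self.f1, "ACS": self.acs, "mode": self.mode},
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion_matrix": self.cm.counts.tolist(),
            "zero_denominator_classes": list(self.zero_denominator_classes),
        }

    def to_text(self) -> str:
        """Percent-scale summary rounded to 2 decimals (display only)."""
        lines = [f"{name} = {100 * val:.2f}%" for name, val in
                 [("A", self.accuracy), ("P", self.precision), ("R", self.recall),
                  ("FS", self.f1), ("ACS", self.acs)]]
        if self.zero_denominator_classes:
            lines.append("zero-denominator classes: "
                         + ", ".join(self.zero_denominator_classes))
        return "\n".join(lines)


def metric_report(true_labels: Sequence[str], predicted_labels: Sequence[str],
                  confidences: Sequence[float], vocabulary: LabelVocabulary,
                  mode: str = "macro") -> MetricReport:
    """Assemble the five-metric report for one prediction set."""
    if len(true_labels) == 0:
        raise ValueError("metric report needs at least one labelled sample")
    cm = confusion_matrix(true_labels, predicted_labels, vocabulary)
    cc = class_counts(cm)
    prec_pc, prec_zero = _per_class_ratio(cc.tp, cc.tp + cc.fp)
    rec_pc, rec_zero = _per_class_ratio(cc.tp, cc.tp + cc.fn)
    f1_pc = np.array([f1(p, r) for p, r in zip(prec_pc, rec_pc)])
    support = cc.tp + cc.fn
    per_class = pd.DataFrame(
        {"precision": prec_pc, "recall": rec_pc, "f1": f1_pc, "support": support},
        index=list(vocabulary),
    )
    p = _aggregate(prec_pc, support, mode)
    r = _aggregate(rec_pc, support, mode)
    zero = tuple(np.asarray(list(vocabulary))[prec_zero | rec_zero])
    return MetricReport(
        accuracy=accuracy(cm), precision=p, recall=r, f1=f1(p, r),
        acs=acs(confidences), mode=mode, per_class=per_class, cm=cm,
        zero_denominator_classes=zero,
    )
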