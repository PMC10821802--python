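"""Confusion-matrix bookkeeping and the accuracy / precision / recall / F1 suite.

The four metrics are computed per class from one-vs-rest counts::

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

and summarized two ways: macro (unweighted mean over classes, the headline
convention for imbalanced multi-class benchmarks) and micro (pooled counts).
Ratios with zero denominator are reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "metrics_from_counts", "compute_metrics"]


@dataclass
class ConfusionCounts:
    """Row = true class, column = predicted class."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(m < 0) or not np.issubdtype(m.dtype, np.integer):
            raise ValueError("confusion matrix must hold non-negative integers")
        self.matrix = m

    @classmethod
    def from_predictions(cls, y_true, y_pred, num_classes: int) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=np.int64)
        y_pred = np.asarray(y_pred, dtype=np.int64)
        m = np.zeros((num_classes, num_classes), dtype=np.int64)
        np.add.at(m, (y_true, y_pred), 1)
        return cls(m)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def num_classes(self) -> int:
        return self.matrix.shape[0]

    def one_vs_rest(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-class (TP, TN, FP, FN) derived from the matrix."""
        tp = np.diag(self.matrix)
        fp = self.matrix.sum(axis=0) - tp
        fn = self.matrix.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn


def metrics_from_counts(tp: float, tn: float, fp: float, fn: float) -> dict[str, float]:
    """The four ratios on one set of binary counts (0 where undefined)."""
    def ratio(num, den):
        return float(num / den) if den > 0 else 0.0

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "precision": precision,
        "recall": recall,
        "f1": ratio(2 * precision * recall, precision + recall),
    }


@dataclass
class MetricsReport:
    """Per-class and averaged metrics, all on the [0, 1] scale."""

    accuracy: float                      # overall = trace / total
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_accuracy: float                # mean one-vs-rest accuracy
    micro_precision: float
    micro_recall: float
    micro_f1: float
    per_class: list[dict[str, float]] = field(default_factory=list)
    undefined_flags: list[str] = field(default_factory=list)

    def as_percent(self) -> dict[str, float]:
        return {k: round(100.0 * getattr(self, k), 4)
                for k in ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                          "micro_precision", "micro_recall", "micro_f1")}


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate the metric suite on a confusion matrix."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    tp, tn, fp, fn = counts.one_vs_rest()
    per_class = []
    flags = []
    for k in range(counts.num_classes):
        m = metrics_from_counts(tp[k], tn[k], fp[k], fn[k])
        if tp[k] + fp[k] == 0:
            flags.append(f"class {k}: precision undefined (no predictions), reported as 0")
        if tp[k] + fn[k] == 0:
            flags.append(f"class {k}: recall undefined (no true samples), reported as 0")
        per_class.append(m)
    macro = {key: float(np.mean([m[key] for m in per_class]))
             for key in ("accuracy", "precision", "recall", "f1")}
    pooled = metrics_from_counts(tp.sum(), tn.sum(), fp.sum(), fn.sum())
    return MetricsReport(
        accuracy=float(np.trace(counts.matrix) / counts.total),
        macro_precision=macro["precision"],
        macro_recall=macro["recall"],
        macro_f1=macro["f1"],
        macro_accuracy=macro["accuracy"],
        micro_precision=pooled["precision"],
        micro_recall=pooled["recall"],
        micro_f1=pooled["f1"],
        per_class=per_class,
        undefined_flags=flags,
    )
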