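"""Accuracy and one-vs-rest precision/recall/F1.

Every class in turn serves as the positive label and all others as
negative, yielding per-class TP/FP/TN/FN counts from which precision,
recall and F1 follow. For single-label prediction the micro-average of
one-vs-rest recall equals plain accuracy. Per-sample inference time is
reported informationally (it is hardware-dependent and never asserted).
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass

import numpy as np

from .preprocessing import WindowedDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single focus class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalReport:
    """Pooled test-set metrics: accuracy plus per-class one-vs-rest P/R/F1."""

    accuracy: float
    class_names: tuple[str, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    confusion: tuple[ConfusionCounts, ...]
    mean_inference_time_per_sample_s: float

    def as_table(self) -> str:
        lines = ["metric\t" + "\t".join(self.class_names)]
        for name, vals in (
            ("precision", self.precision),
            ("recall", self.recall),
            ("f1", self.f1),
        ):
            lines.append(name + "\t" + "\t".join(f"{v:.4f}" for v in vals))
        lines.insert(0, f"accuracy\t{self.accuracy:.4f}")
        lines.append(
            f"time_per_sample_s\t{self.mean_inference_time_per_sample_s:.6f}"
        )
        return "\n".join(lines)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting 0")
        return 0.0
    return num / den


def one_vs_rest_counts(y_true, y_pred, focus_class, classes=None) -> ConfusionCounts:
    """TP/FP/TN/FN with ``focus_class`` as positive, everything else negative."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is not None:
        known = set(np.asarray(classes).tolist())
        bad = (set(y_true.tolist()) | set(y_pred.tolist())) - known
        if bad:
            raise ValueError(f"unknown label value(s): {sorted(map(str, bad))}")
        if focus_class not in known:
            raise ValueError(f"unknown focus class {focus_class!r}")
    pos_t = y_true == focus_class
    pos_p = y_pred == focus_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def metrics_from_counts(c: ConfusionCounts) -> tuple[float, float, float]:
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    return precision, recall, f1


def report_from_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    class_names: list[str],
    mean_inference_time_per_sample_s: float = float("nan"),
) -> EvalReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.arange(len(class_names))
    accuracy = float(np.mean(y_true == y_pred))
    counts = tuple(
        one_vs_rest_counts(y_true, y_pred, k, classes=classes) for k in classes
    )
    prf = [metrics_from_counts(c) for c in counts]
    return EvalReport(
        accuracy=accuracy,
        class_names=tuple(class_names),
        precision=tuple(p for p, _, _ in prf),
        recall=tuple(r for _, r, _ in prf),
        f1=tuple(f for _, _, f in prf),
        confusion=counts,
        mean_inference_time_per_sample_s=mean_inference_time_per_sample_s,
    )


def evaluate(net, test: WindowedDataset, batch_size: int = 256) -> EvalReport:
    """Predict test windows (argmax of softmax; ties resolve to the
    lowest class index) and compute the pooled metrics."""
    if test.n_windows == 0:
        raise ValueError("test set must be non-empty")
    t0 = time.perf_counter()
    proba = net.predict_proba(test.windows, batch_size=batch_size)
    elapsed = time.perf_counter() - t0
    y_pred = proba.argmax(axis=1)
    return report_from_predictions(
        test.labels, y_pred, list(test.class_names), elapsed / test.n_windows
    )
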