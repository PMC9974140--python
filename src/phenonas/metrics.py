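"""Evaluation metrics: confusion-matrix classification scores and
regression R^2 / MSE.

``r2`` exposes two variants.  ``standard`` is the conventional coefficient
of determination ``1 - SS_res / SS_tot``.  ``as_printed`` is the
explained-variance ratio ``sum((yhat_i - ybar)^2) / sum((y_i - ybar)^2)``
sometimes printed in place of R^2; the two coincide for least-squares fits
with intercept but differ in general, and the ratio form is not bounded by
1 for arbitrary predictors.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "RegressionEvalInput",
    "confusion",
    "accuracy",
    "precision_recall_f1",
    "r2",
    "mse",
    "confusion_to_csv",
    "metric_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self) -> dict[str, np.ndarray]:
        """Per-class TP/FP/FN/TN; each class's four counts sum to total."""
        c = self.counts
        tp = np.diag(c)
        fp = c.sum(axis=0) - tp
        fn = c.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


@dataclass(frozen=True)
class RegressionEvalInput:
    """True values, predictions, and the derived mean and sample count."""

    y: np.ndarray
    y_hat: np.ndarray

    def __post_init__(self) -> None:
        y, y_hat = np.asarray(self.y, float), np.asarray(self.y_hat, float)
        if y.shape != y_hat.shape or y.ndim != 1:
            raise ValueError("y and y_hat must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def y_bar(self) -> float:
        return float(np.mean(self.y))


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for arr, label in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{label} contains labels outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions, trace / total.  For two classes this
    is exactly (TP + TN) / (TP + TN + FP + FN)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def precision_recall_f1(cm: ConfusionMatrix, averaging: str = "macro") -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN) and their harmonic-mean F1,
    macro- or micro-averaged.  A class with a zero denominator contributes 0
    and triggers a warning."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if averaging not in ("macro", "micro"):
        raise ValueError("averaging must be 'macro' or 'micro'")
    pc = cm.per_class()
    tp, fp, fn = pc["tp"].astype(float), pc["fp"].astype(float), pc["fn"].astype(float)
    if averaging == "micro":
        precision = tp.sum() / (tp.sum() + fp.sum())
        recall = tp.sum() / (tp.sum() + fn.sum())
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            p_cls = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 0.0)
            r_cls = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1e-300), 0.0)
        if ((tp + fp) == 0).any() or ((tp + fn) == 0).any():
            warnings.warn("classes with zero denominator contribute 0 to macro averages")
        precision, recall = float(p_cls.mean()), float(r_cls.mean())
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return float(precision), float(recall), float(f1)


def r2(inp: RegressionEvalInput, variant: str = "standard") -> float:
    """Coefficient of determination.

    ``standard``: ``1 - sum((y - yhat)^2) / sum((y - ybar)^2)``.
    ``as_printed``: ``sum((yhat - ybar)^2) / sum((y - ybar)^2)``.
    Both equal 1 for perfect predictions; constant ``y`` is undefined.
    """
    if inp.n < 2:
        raise ValueError("R^2 needs at least 2 samples")
    y = np.asarray(inp.y, float)
    y_hat = np.asarray(inp.y_hat, float)
    ss_tot = float(((y - inp.y_bar) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant y")
    if variant == "standard":
        return 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot
    if variant == "as_printed":
        return float(((y_hat - inp.y_bar) ** 2).sum()) / ss_tot
    raise ValueError("variant must be 'standard' or 'as_printed'")


def mse(inp: RegressionEvalInput) -> float:
    """Mean squared error, ``(1/n) sum((y_i - yhat_i)^2)``."""
    if inp.n < 1:
        raise ValueError("MSE needs at least 1 sample")
    y = np.asarray(inp.y, float)
    y_hat = np.asarray(inp.y_hat, float)
    return float(((y - y_hat) ** 2).mean())


def confusion_to_csv(cm: ConfusionMatrix, path: str | Path, labels: list[str] | None = None) -> None:
    labels = labels or [str(i) for i in range(cm.n_classes)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred", *labels])
        for i, row in enumerate(cm.counts):
            writer.writerow([labels[i], *row.tolist()])


def metric_report(
    cm: ConfusionMatrix,
    count_eval: RegressionEvalInput,
    area_eval: RegressionEvalInput,
    averaging: str = "macro",
) -> dict[str, float]:
    """All headline metrics of the three tasks in one dict."""
    precision, recall, f1 = precision_recall_f1(cm, averaging)
    return {
        "accuracy": accuracy(cm),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "count_r2": r2(count_eval),
        "count_mse": mse(count_eval),
        "area_r2": r2(area_eval),
        "area_mse": mse(area_eval),
    }
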