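"""Evaluation metrics and model comparison.

Metrics are computed from one-vs-rest confusion tallies per class:
accuracy is the fraction of correct predictions; precision TP/(TP+FP) and
recall TP/(TP+FN) are computed per class and macro-averaged; macro F1 is
the unweighted mean of per-class F1 = 2PR/(P+R).  A class with an undefined
precision, recall or F1 (zero denominator) scores 0 for that quantity —
the standard convention under severe imbalance, which makes macro scores
sensitive to classes the classifier never predicts.

``compare_models`` is the paired two-sided t-test on per-class F1 scores,
the unit at which two classifiers over the same categories are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/FN/TN tallies."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        if self.n_classes == 0:
            return 0
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


@dataclass(frozen=True)
class MetricReport:
    """Overall metrics plus the per-class precision/recall/F1 table."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: pd.DataFrame


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> ConfusionCounts:
    """One-vs-rest confusion tallies for every class in [0, n_classes)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (
        y_true.min() < 0
        or y_true.max() >= n_classes
        or y_pred.min() < 0
        or y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    total = y_true.size
    tp = np.zeros(n_classes, dtype=int)
    fp = np.zeros(n_classes, dtype=int)
    fn = np.zeros(n_classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        if t == p:
            tp[t] += 1
        else:
            fn[t] += 1
            fp[p] += 1
    tn = total - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, macro precision/recall/F1 and the per-class table."""
    total = counts.total
    if total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(
            counts.tp + counts.fp > 0, counts.tp / (counts.tp + counts.fp), 0.0
        )
        recall = np.where(
            counts.tp + counts.fn > 0, counts.tp / (counts.tp + counts.fn), 0.0
        )
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    per_class = pd.DataFrame(
        {
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "tn": counts.tn,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    )
    return MetricReport(
        accuracy=float(counts.tp.sum() / total),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        per_class=per_class,
    )


def compare_models(
    per_class_f1_a: np.ndarray, per_class_f1_b: np.ndarray
) -> tuple[float, float]:
    """Paired two-sided t-test on per-class F1 scores of two models.

    Returns (t statistic, p-value).  Identical vectors give t = 0, p = 1.
    Nonzero differences with zero variance have an infinite statistic; the
    p-value is then reported as 0.0 (the epsilon-guarded limit).
    """
    a = np.asarray(per_class_f1_a, dtype=float)
    b = np.asarray(per_class_f1_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two paired scores")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    if np.isclose(diff.std(ddof=1), 0.0):
        return float(np.inf * np.sign(diff.mean())), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
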