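"""Phenotype-algorithm validation against a probabilistic reference standard.

Instead of chart-adjudicated case labels, each person carries a model-
assigned probability of truly being a case.  Confusion-matrix cells are
then sums of those conditional probabilities over flagged/unflagged
persons, which yields real-valued TP/FP/FN/TN and the usual
misclassification metrics.  When every probability is 0 or 1 this reduces
exactly to the deterministic confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ProbabilisticConfusionMatrix:
    tp: float
    tn: float
    fp: float
    fn: float


@dataclass(frozen=True)
class MisclassificationMetrics:
    """Sensitivity, specificity, PPV, NPV; NaN marks an undefined ratio."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def probabilistic_confusion(case_probs: np.ndarray, flagged: np.ndarray
                            ) -> ProbabilisticConfusionMatrix:
    """Confusion cells as sums of case probabilities.

    tp = sum of p over flagged persons, fp = sum of (1-p) over flagged,
    fn = sum of p over unflagged, tn = sum of (1-p) over unflagged.
    """
    p = np.asarray(case_probs, dtype=float)
    f = np.asarray(flagged, dtype=bool)
    if p.shape != f.shape:
        raise ValueError("case_probs and flagged must have equal length")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("case probabilities must lie in [0, 1]")
    return ProbabilisticConfusionMatrix(
        tp=float(p[f].sum()), fp=float((1 - p[f]).sum()),
        fn=float(p[~f].sum()), tn=float((1 - p[~f]).sum()))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def misclassification_metrics(cm: ProbabilisticConfusionMatrix
                              ) -> MisclassificationMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
    NPV TN/(TN+FN); a zero denominator yields NaN."""
    return MisclassificationMetrics(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn))
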