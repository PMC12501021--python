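"""Confusion-matrix construction and multiclass evaluation metrics.

Per-class rates use one-vs-rest bookkeeping from a K x K confusion matrix
(rows = true class, columns = predicted class):

    precision   = TP / (TP + FP) * 100
    sensitivity = TP / (TP + FN) * 100          (recall)
    specificity = TN / (TN + FP) * 100
    ovr_accuracy = (TP + TN) / n * 100          (one-vs-rest accuracy)

Published per-class "accuracy" figures in this problem domain usually track
per-class recall (correct predictions over the class's row total), so that
quantity is exposed separately as ``class_accuracy``; both columns are
reported to avoid ambiguity. Overall rows are unweighted macro means across
classes (micro accuracy = trace/n is reported separately). ROC-AUC is the
rank statistic (probability a random positive outscores a random negative,
ties counting one half); the printed TPR/FPR ratio sometimes labelled "AUC"
is exposed verbatim as ``tpr_fpr_ratio`` but is not an AUC. McNemar's paired
test compares two classifiers on the same samples via their discordant
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "confusion_matrix",
    "class_metrics",
    "macro_overall",
    "micro_accuracy",
    "roc_auc",
    "roc_auc_ovr",
    "tpr_fpr_ratio",
    "PairedPredictions",
    "mcnemar_test",
    "two_proportion_z_test",
]


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Exact integer count matrix of (true, predicted) label pairs."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_rate(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, 100.0 * num / den, np.nan)


def class_metrics(cm: np.ndarray, class_names=None) -> pd.DataFrame:
    """One-vs-rest counts and rates per class (percentages; NaN if undefined)."""
    cm = np.asarray(cm)
    if cm.size == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    n = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = n - tp - fp - fn
    df = pd.DataFrame({
        "tp": tp.astype(int), "fp": fp.astype(int),
        "fn": fn.astype(int), "tn": tn.astype(int),
        "precision": _safe_rate(tp, tp + fp),
        "ovr_accuracy": _safe_rate(tp + tn, np.full(k, float(n))),
        "sensitivity": _safe_rate(tp, tp + fn),
        "specificity": _safe_rate(tn, tn + fp),
        "class_accuracy": _safe_rate(tp, cm.sum(axis=1).astype(float)),
    })
    if class_names is not None:
        df.index = list(class_names)
    return df


def macro_overall(per_class_values) -> float:
    """Unweighted mean across classes, rounded to 2 decimals for reporting."""
    values = np.asarray(per_class_values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one class")
    return round(float(values.mean()), 2)


def micro_accuracy(cm: np.ndarray) -> float:
    """Overall multiclass accuracy: trace / n * 100."""
    cm = np.asarray(cm)
    return 100.0 * float(np.trace(cm)) / float(cm.sum())


def roc_auc(labels, scores) -> float:
    """Rank-based ROC-AUC: P(score_pos > score_neg) with ties counting 1/2."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc_ovr(y_true, score_matrix) -> np.ndarray:
    """One-vs-rest AUC per class from an (n, K) score matrix."""
    y_true = np.asarray(y_true, dtype=int)
    score_matrix = np.asarray(score_matrix, dtype=float)
    k = score_matrix.shape[1]
    return np.array([roc_auc(y_true == c, score_matrix[:, c]) for c in range(k)])


def tpr_fpr_ratio(tp: int, fn: int, fp: int, tn: int) -> float:
    """The literal TPR/FPR ratio (not an AUC; infinite when FPR is zero)."""
    tpr = tp / (tp + fn) if tp + fn else np.nan
    fpr = fp / (fp + tn) if fp + tn else np.nan
    return float(np.inf) if fpr == 0 else float(tpr / fpr)


@dataclass(frozen=True)
class PairedPredictions:
    """Discordant counts of two classifiers on the same samples.

    b: samples model A got right and model B got wrong; c: the reverse.
    """

    b: int
    c: int

    def __post_init__(self):
        if self.b < 0 or self.c < 0:
            raise ValueError("discordant counts must be nonnegative")

    @classmethod
    def from_correctness(cls, a_correct, b_correct) -> "PairedPredictions":
        a = np.asarray(a_correct, dtype=bool)
        b = np.asarray(b_correct, dtype=bool)
        if a.shape != b.shape:
            raise ValueError("paired correctness vectors differ in length")
        return cls(b=int((a & ~b).sum()), c=int((~a & b).sum()))


def mcnemar_test(paired: PairedPredictions | tuple[int, int],
                 method: str = "auto") -> tuple[float, float]:
    """McNemar's paired test -> (statistic, p-value).

    method "chi2": continuity-corrected chi^2 = (max(|b-c|-1, 0))^2 / (b+c),
    p from the chi^2(1) survival function. method "exact": two-sided binomial
    test on b out of b+c at p=0.5 (statistic reported as min(b, c)).
    "auto" uses the exact variant when b + c < 25.
    """
    if not isinstance(paired, PairedPredictions):
        paired = PairedPredictions(*paired)
    b, c = paired.b, paired.c
    if b + c == 0:
        raise ValueError("no discordant pairs: McNemar's test is undefined")
    if method == "auto":
        method = "exact" if b + c < 25 else "chi2"
    if method == "chi2":
        statistic = max(abs(b - c) - 1, 0) ** 2 / (b + c)
        return float(statistic), float(stats.chi2.sf(statistic, df=1))
    if method == "exact":
        p = stats.binomtest(min(b, c), b + c, 0.5, alternative="two-sided").pvalue
        return float(min(b, c)), float(min(1.0, p))
    raise ValueError(f"unknown method {method!r}")


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sided z-test for equality of two proportions (pooled variance)."""
    if min(n1, n2) <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))
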