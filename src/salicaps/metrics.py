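"""Threshold-dependent classification metrics and threshold selection.

accuracy   = (TP + TN) / N_total
sensitivity = recall = TP / (TP + FN)
specificity = TN / (TN + FP)
precision  = TP / (TP + FP)
F-score    = 2 * precision * recall / (precision + recall)
MCC        = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

All metrics depend on the decision threshold; the operating threshold is
chosen where the MCC is maximal over the finite sweep of candidate
thresholds (midpoints between adjacent unique scores, plus sentinels beyond
the extremes).  A sample is predicted positive when score >= threshold.

Metrics with a zero denominator are reported as 0 and flagged rather than
propagating NaN, so they aggregate stably across bagging iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import precision_recall_curve as _sk_pr
from sklearn.metrics import roc_curve as _sk_roc


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN at a fixed decision threshold."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_total < 1:
            raise ValueError("at least one sample is required")

    @property
    def n_total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class SingleClassError(ValueError):
    """Raised when a ranking metric needs both classes but got one."""


class DegenerateDifferencesError(ValueError):
    """Raised by the paired t-test when the differences have zero variance."""


def _check_scored(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D arrays")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be 0/1")
    return scores, labels


def confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts with the decision rule: positive iff score >= threshold."""
    scores, labels = _check_scored(scores, labels)
    predicted = scores >= threshold
    actual = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(predicted & actual)),
        tn=int(np.sum(~predicted & ~actual)),
        fp=int(np.sum(predicted & ~actual)),
        fn=int(np.sum(~predicted & actual)),
    )


def _safe_div(num: float, den: float, flags: set[str], name: str) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> dict:
    """All six threshold metrics from confusion counts.

    Returns a dict with keys accuracy, sensitivity, specificity, precision,
    f_score, mcc, and 'flags': the set of metric names whose denominator was
    zero (reported as 0).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    flags: set[str] = set()
    accuracy = (tp + tn) / counts.n_total
    sensitivity = _safe_div(tp, tp + fn, flags, "sensitivity")
    specificity = _safe_div(tn, tn + fp, flags, "specificity")
    precision = _safe_div(tp, tp + fp, flags, "precision")
    f_score = _safe_div(
        2.0 * precision * sensitivity, precision + sensitivity, flags, "f_score"
    )
    mcc_den = np.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(float(tp) * tn - float(fp) * fn, mcc_den, flags, "mcc")
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "f_score": f_score,
        "mcc": mcc,
        "flags": flags,
    }


def roc_and_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR at each unique-score threshold) and trapezoidal AUC."""
    scores, labels = _check_scored(scores, labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc(labels, scores, drop_intermediate=False)
    return fpr, tpr, float(_auc(fpr, tpr))


def precision_recall_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Precision and recall at each unique-score threshold.

    Recall is nonincreasing as the threshold rises (returned in threshold
    order, i.e. recall-decreasing order).
    """
    scores, labels = _check_scored(scores, labels)
    if labels.sum() == 0:
        raise SingleClassError("precision-recall needs at least one positive")
    precision, recall, _ = _sk_pr(labels, scores)
    return precision, recall


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints of adjacent unique scores, plus sentinels beyond both ends."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])


def select_threshold_max_mcc(scores, labels) -> float:
    """The decision threshold at which the MCC is maximal.

    Candidates are midpoints between adjacent unique scores with sentinels
    below the minimum (predict everything positive) and above the maximum
    (predict everything negative); ties in MCC resolve to the smallest
    candidate.
    """
    scores, labels = _check_scored(scores, labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("MCC threshold selection needs both classes")
    best_thr = None
    best_mcc = -np.inf
    for thr in _candidate_thresholds(scores):
        value = metrics(confusion_at(scores, labels, thr))["mcc"]
        if value > best_mcc + 1e-12:
            best_mcc = value
            best_thr = float(thr)
    return best_thr


def metrics_at_max_mcc(scores, labels) -> dict:
    """Convenience: all metrics at the max-MCC operating threshold."""
    thr = select_threshold_max_mcc(scores, labels)
    out = metrics(confusion_at(scores, labels, thr))
    out["threshold"] = thr
    return out


def paired_ttest(metric_a, metric_b) -> float:
    """Two-sided paired t-test p-value on per-iteration metric differences.

    Identical lists give p = 1.  A constant nonzero difference (zero variance
    of the differences) is degenerate and raises
    :class:`DegenerateDifferencesError`.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length lists of >= 2 values")
    d = a - b
    if np.std(d) == 0.0:
        if np.all(d == 0.0):
            return 1.0
        raise DegenerateDifferencesError(
            "paired differences are constant and nonzero"
        )
    return float(stats.ttest_rel(a, b).pvalue)
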