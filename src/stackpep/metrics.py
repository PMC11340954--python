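"""Evaluation measures and MCC-maximising threshold selection.

Seven measures are reported for every model: sensitivity, specificity,
precision, accuracy, Matthews correlation coefficient (threshold-dependent)
plus the threshold-free ROC AUC and precision-recall AUC. The operating
threshold is not fixed at 0.5: it is chosen to maximise MCC over the
training out-of-fold probabilities, which matters under the heavy class
imbalance this toolkit targets (a trivial all-negative classifier already
scores high accuracy there).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["MetricsReport", "confusion_metrics", "roc_auc", "pr_auc",
           "mcc_optimal_threshold", "evaluate_probabilities"]


@dataclass
class MetricsReport:
    """Confusion counts and the seven evaluation measures at a threshold."""

    TP: int
    FP: int
    TN: int
    FN: int
    SEN: float
    SPE: float
    PRE: float
    ACC: float
    MCC: float
    AUC: float = float("nan")
    AUPRC: float = float("nan")
    threshold: float = float("nan")
    precision_defined: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def _check(labels, probs):
    labels = np.asarray(labels, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != probs.shape:
        raise ValueError("labels and probs must align")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    return labels, probs


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    defined as 0 when any factor of the denominator is 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def confusion_metrics(labels, probs, threshold: float) -> MetricsReport:
    """Threshold-dependent measures; a sample is called positive when its
    probability is >= threshold. Undefined precision (no positive calls)
    is reported as 0 with ``precision_defined=False``."""
    labels, probs = _check(labels, probs)
    pred = probs >= threshold
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & neg))
    tn = int(np.sum(~pred & neg))
    fn = int(np.sum(~pred & pos))
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    pre_defined = (tp + fp) > 0
    pre = tp / (tp + fp) if pre_defined else 0.0
    acc = (tp + tn) / labels.size
    return MetricsReport(tp, fp, tn, fn, sen, spe, pre, acc,
                         mcc_from_counts(tp, fp, tn, fn),
                         threshold=threshold, precision_defined=pre_defined)


def roc_auc(labels, probs) -> float:
    """Rank-statistic ROC AUC (ties contribute one half)."""
    labels, probs = _check(labels, probs)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for AUC")
    return float(roc_auc_score(labels, probs))


def pr_auc(labels, probs) -> float:
    """Precision-recall AUC via step integration (average precision)."""
    labels, probs = _check(labels, probs)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for AUPRC")
    return float(average_precision_score(labels, probs))


def mcc_optimal_threshold(labels, probs) -> float:
    """Threshold maximising MCC.

    Candidates are every distinct probability plus 0 and 1 (a sample is
    positive when prob >= threshold, so each candidate realises a distinct
    confusion table). The smallest maximising candidate is returned.
    """
    labels, probs = _check(labels, probs)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    candidates = np.unique(np.concatenate([probs, [0.0, 1.0]]))
    best_theta, best_mcc = candidates[0], -np.inf
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    order = np.argsort(probs, kind="stable")
    sorted_probs = probs[order]
    sorted_labels = labels[order]
    # cumulative counts below each candidate give the confusion table in O(n log n)
    for theta in candidates:
        k = np.searchsorted(sorted_probs, theta, side="left")
        fn = int(np.sum(sorted_labels[:k] == 1))
        tn = k - fn
        tp = n_pos - fn
        fp = n_neg - tn
        mcc = mcc_from_counts(tp, fp, tn, fn)
        if mcc > best_mcc + 1e-12:
            best_mcc, best_theta = mcc, theta
    return float(best_theta)


def evaluate_probabilities(labels, probs,
                           threshold: float | None = None) -> MetricsReport:
    """Full report: MCC-optimal threshold (unless given), the five
    threshold-dependent measures at it, plus AUC and AUPRC."""
    labels, probs = _check(labels, probs)
    if threshold is None:
        threshold = mcc_optimal_threshold(labels, probs)
    report = confusion_metrics(labels, probs, threshold)
    report.AUC = roc_auc(labels, probs)
    report.AUPRC = pr_auc(labels, probs)
    return report
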