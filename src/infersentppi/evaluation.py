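"""Classification metrics: accuracy/precision/recall/F1 and ROC/PR areas.

Curves and areas are delegated to scikit-learn: ROC with tied scores
grouped into single steps and trapezoidal area; PR area as average
precision, i.e. the step-wise (achievable-precision) rectangle rule over
recall increments rather than trapezoids — the two differ and the
step-wise form is the one reported here. Threshold metrics guard zero
denominators by returning 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn import metrics as _skm


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float | None
    auc_pr: float | None
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, returning 0")
        return 0.0
    return num / den


def confusion_metrics(labels, predicted) -> MetricsReport:
    """Threshold metrics from hard 0/1 predictions (no ranking metrics)."""
    labels = np.asarray(labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label list")
    if labels.shape != predicted.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {predicted.shape}")
    tp = int(np.sum((labels == 1) & (predicted == 1)))
    tn = int(np.sum((labels == 0) & (predicted == 0)))
    fp = int(np.sum((labels == 0) & (predicted == 1)))
    fn = int(np.sum((labels == 1) & (predicted == 0)))
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    return MetricsReport(
        accuracy=(tp + tn) / labels.size,
        precision=precision,
        recall=recall,
        f1=f1,
        auc_roc=None,
        auc_pr=None,
        n_pos=int(labels.sum()),
        n_neg=int(labels.size - labels.sum()),
    )


def roc_curve(labels, scores):
    """ROC points (FPR, TPR) at descending distinct-score thresholds, and the area."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC requires both classes in the labels")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    auc = float(_skm.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def pr_curve(labels, scores):
    """PR points (Recall, Precision) and the step-wise area (average precision)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        raise ValueError("PR curve requires at least one positive label")
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    auc = float(_skm.average_precision_score(labels, scores))
    return list(zip(recall.tolist(), precision.tolist())), auc


def full_report(labels, scores, predicted=None) -> MetricsReport:
    """Threshold metrics (at 0.5 on scores unless ``predicted`` given) plus AUCs."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if predicted is None:
        predicted = (scores > 0.5).astype(int)
    rep = confusion_metrics(labels, predicted)
    if len(set(labels.tolist())) == 2:
        _, rep.auc_roc = roc_curve(labels, scores)
        _, rep.auc_pr = pr_curve(labels, scores)
    return rep


def best_threshold(labels, scores) -> float:
    """Score cut-off maximising accuracy (used to threshold baseline scores).

    Candidate thresholds are midpoints between consecutive distinct scores;
    prediction is ``score > threshold``. Ties broken toward the lowest
    threshold (higher recall).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    cands = np.concatenate(([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0))
    best_t, best_acc = cands[0], -1.0
    for t in cands:
        acc = float(np.mean((scores > t).astype(int) == labels))
        if acc > best_acc:
            best_acc, best_t = acc, t
    return float(best_t)
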