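"""Classifier evaluation for screening indices: confusion matrices,
precision/recall/F-score, ROC and precision-recall curves, and the
F-score-maximizing threshold scan.

Threshold convention: a compound scoring at or above the threshold is
predicted positive (the printed operating threshold is inclusive).
Undefined ratios (0/0) are reported as ``None``, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true/false positives/negatives at one operating point."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    """TPR (= recall), FPR, precision and F-score for one confusion matrix.

    A field is ``None`` when its denominator is zero (undefined, not 0).
    """

    tpr: float | None
    fpr: float | None
    precision: float | None
    f_score: float | None

    @property
    def recall(self) -> float | None:
        return self.tpr


@dataclass(frozen=True)
class Curve:
    """An ROC or precision-recall curve with its trapezoidal AUC."""

    points: np.ndarray  # (n, 2): ROC (FPR, TPR); PR (recall, precision)
    auc: float
    kind: str  # "roc" or "pr"


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Recall, FPR, precision and F-score:

        TPR = TP / (TP + FN)      FPR = FP / (FP + TN)
        Precision = TP / (TP + FP)
        F = 2 TP / (2 TP + FP + FN)
    """
    tpr = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    fpr = cm.fp / (cm.fp + cm.tn) if cm.fp + cm.tn else None
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else None
    denom = 2 * cm.tp + cm.fp + cm.fn
    f_score = 2 * cm.tp / denom if denom else None
    return MetricSet(tpr=tpr, fpr=fpr, precision=precision, f_score=f_score)


def confusion_at_threshold(
    pos_scores: Sequence[float], neg_scores: Sequence[float], threshold: float
) -> ConfusionMatrix:
    """Confusion matrix with 'score >= threshold' predicted positive."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    tp = int(np.sum(pos >= threshold))
    fp = int(np.sum(neg >= threshold))
    return ConfusionMatrix(tp=tp, fp=fp, fn=pos.size - tp, tn=neg.size - fp)


def _threshold_sweep(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Candidate thresholds: every distinct observed score, descending."""
    return np.unique(np.concatenate([pos, neg]))[::-1]


def roc_curve(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> Curve:
    """ROC curve over all distinct observed scores plus a sentinel above the
    maximum; points are (FPR, TPR), AUC by the trapezoidal rule.

    With this sweep the trapezoidal AUC equals the Mann–Whitney statistic
    U / (n_pos * n_neg) with ties counted half.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    points = [(0.0, 0.0)]  # sentinel threshold above every score
    for t in _threshold_sweep(pos, neg):
        tp = np.sum(pos >= t)
        fp = np.sum(neg >= t)
        points.append((fp / neg.size, tp / pos.size))
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return Curve(points=pts, auc=auc, kind="roc")


def pr_curve(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> Curve:
    """Precision-recall curve over the same threshold sweep; points are
    (recall, precision), listed from the highest threshold down.

    The AUC is the trapezoid over recall with an implicit anchor at recall 0
    carrying the precision of the first (highest-threshold) point; no other
    interpolation is applied.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    points = []
    for t in _threshold_sweep(pos, neg):
        tp = np.sum(pos >= t)
        fp = np.sum(neg >= t)
        points.append((tp / pos.size, tp / (tp + fp)))  # tp+fp >= 1 at observed scores
    pts = np.array(points)
    anchored = np.vstack([[0.0, pts[0, 1]], pts])
    auc = float(np.trapezoid(anchored[:, 1], anchored[:, 0]))
    return Curve(points=pts, auc=auc, kind="pr")


def best_threshold_by_fscore(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[float, float]:
    """Scan every distinct observed score as a candidate threshold and
    return the one maximizing the F-score (ties -> smallest threshold)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    best_t, best_f = None, -1.0
    for t in np.unique(np.concatenate([pos, neg])):  # ascending: first win is smallest
        m = metrics(confusion_at_threshold(pos, neg, t))
        if m.f_score is not None and m.f_score > best_f:
            best_t, best_f = float(t), float(m.f_score)
    if best_t is None:
        raise ValueError("no threshold yields a defined F-score")
    return best_t, best_f


def ro4_operating_points(
    pos_violations: Sequence[int], neg_violations: Sequence[int]
) -> list[dict]:
    """Confusion matrices and metrics for the rule-of-four at 0..4 allowed
    violations, for overlay on ROC / PR curves."""
    pos = np.asarray(pos_violations)
    neg = np.asarray(neg_violations)
    out = []
    for allowed in range(5):
        tp = int(np.sum(pos <= allowed))
        fp = int(np.sum(neg <= allowed))
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=pos.size - tp, tn=neg.size - fp)
        m = metrics(cm)
        out.append({"allowed_violations": allowed, "confusion": cm, "metrics": m})
    return out
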