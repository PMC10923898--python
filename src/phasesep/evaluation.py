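"""ROC/PRC evaluation, threshold selection, and confusion-matrix metrics."""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.metrics import auc, average_precision_score, precision_recall_curve, roc_curve


@dataclasses.dataclass
class MetricsReport:
    auroc: float
    auprc: float
    threshold: float
    mcc: float
    f1: float
    sensitivity: float
    specificity: float
    accuracy: float
    fpr: float
    fnr: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


def roc_prc(scores: Sequence[float], labels: Sequence[int]):
    """ROC and PRC curves with their areas.

    Returns ``(fpr, tpr, roc_thresholds), (precision, recall), auroc, auprc``.
    AUROC is trapezoidal over the tie-grouped ROC curve; AUPRC is the
    step-wise integral (average precision).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auroc = float(auc(fpr, tpr))
    precision, recall, _ = precision_recall_curve(labels, scores)
    auprc = float(average_precision_score(labels, scores))
    return (fpr, tpr, thr), (precision, recall), auroc, auprc


def select_threshold(
    fpr: Sequence[float], tpr: Sequence[float], thresholds: Sequence[float]
) -> float:
    """Score threshold of the ROC point nearest the top-left corner.

    Distance = sqrt(FPR² + (1 − TPR)²); ties resolved toward the
    higher-specificity (lower FPR) point.  The synthetic leading point
    emitted by scikit-learn (threshold = inf) is excluded.
    """
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    valid = np.isfinite(thresholds)
    fpr, tpr, thresholds = fpr[valid], tpr[valid], thresholds[valid]
    dist = np.hypot(fpr, 1.0 - tpr)
    order = np.lexsort((fpr, dist))  # min distance, then min FPR
    return float(thresholds[order[0]])


def binary_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
) -> MetricsReport:
    """Confusion-matrix metrics at ``score >= threshold`` → positive."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))

    n_pos, n_neg = tp + fn, fp + tn
    sensitivity = tp / n_pos if n_pos else 0.0
    specificity = tn / n_neg if n_neg else 0.0
    accuracy = (tp + tn) / len(labels) if len(labels) else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0

    if len(set(labels.tolist())) == 2:
        _, _, auroc, auprc = roc_prc(scores, labels)
    else:  # confusion metrics remain defined for single-class inputs
        auroc = auprc = math.nan
    return MetricsReport(
        auroc=auroc,
        auprc=auprc,
        threshold=float(threshold),
        mcc=float(mcc),
        f1=float(f1),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        accuracy=float(accuracy),
        fpr=1.0 - specificity,
        fnr=1.0 - sensitivity,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def evaluate(scores: Sequence[float], labels: Sequence[int]) -> MetricsReport:
    """Full report with the nearest-top-left threshold."""
    (fpr, tpr, thr), _, _, _ = roc_prc(scores, labels)
    threshold = select_threshold(fpr, tpr, thr)
    return binary_metrics(scores, labels, threshold)


def mlo_protocol(
    mlo_positive_ids: Iterable[str],
    training_positive_ids: Iterable[str],
    negative_test_scores: Dict[str, float],
    scores: Dict[str, float],
    idr_class: Dict[str, str],
) -> Dict[str, Optional[MetricsReport]]:
    """Per-class evaluation against an MLO membership set.

    Positives are MLO proteins not used in training, split into ID/noID
    via ``idr_class``; negatives are the held-out negative test set.
    Classes left empty after the exclusion are reported as None.
    """
    mlo: Set[str] = set(mlo_positive_ids) - set(training_positive_ids)
    out: Dict[str, Optional[MetricsReport]] = {}
    for cls in ("ID", "noID"):
        pos_ids = [p for p in mlo if idr_class.get(p) == cls and p in scores]
        if not pos_ids:
            out[cls] = None
            continue
        y = [1] * len(pos_ids) + [0] * len(negative_test_scores)
        s = [scores[p] for p in pos_ids] + list(negative_test_scores.values())
        out[cls] = evaluate(s, y)
    return out
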