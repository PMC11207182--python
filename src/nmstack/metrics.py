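"""Binary-classification evaluation measures.

Threshold metrics (SEN, SPE, PRE, ACC, MCC) follow the standard confusion
count definitions; a score equal to the threshold counts as a predicted
positive (the 0.5-inclusive site-call convention). AUC uses the
rank / Mann-Whitney formulation (ties count one half) rather than
trapezoidal ROC integration, so tied scores are handled exactly; AUPRC is
the step-wise precision-recall integral.

Degenerate denominators yield 0 with a logged warning rather than NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> ConfusionCounts:
    """Count confusion cells; ``score >= threshold`` is a predicted positive."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(
            f"length mismatch: {labels.shape[0]} labels vs {scores.shape[0]} scores"
        )
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s denominator is zero; returning 0", name)
        return 0.0
    return num / den


def summary(cc: ConfusionCounts) -> dict[str, float]:
    """SEN, SPE, PRE, ACC and MCC from confusion counts."""
    tp, fp, tn, fn = cc.tp, cc.fp, cc.tn, cc.fn
    mcc_den = math.sqrt(
        float(tn + fn) * float(tp + fp) * float(tn + fp) * float(tp + fn)
    )
    return {
        "SEN": _safe_div(tp, tp + fn, "SEN"),
        "SPE": _safe_div(tn, tn + fp, "SPE"),
        "PRE": _safe_div(tp, tp + fp, "PRE"),
        "ACC": _safe_div(tp + tn, cc.total, "ACC"),
        "MCC": _safe_div(tp * tn - fp * fn, mcc_den, "MCC"),
    }


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """P(random positive outranks random negative), ties counting one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties exactly
    rank_sum = float(np.sum(ranks[labels == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve by step-wise integration.

    Thresholds descend through the distinct scores; the area is
    sum over steps of (recall_i - recall_{i-1}) * precision_i, the same
    step-wise sum as average precision.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("auprc requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    # collapse tied scores: only the last index of each tie block is a
    # valid operating point
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def evaluate_scores(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> dict[str, float]:
    """All seven measures: SEN, SPE, PRE, ACC, MCC, AUC, AUPRC."""
    out = summary(confusion(labels, scores, threshold))
    out["AUC"] = roc_auc(labels, scores)
    out["AUPRC"] = auprc(labels, scores)
    return out
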