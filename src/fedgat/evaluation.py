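"""Multi-label evaluation metrics.

Per-label ROC-AUC (macro-averaged over non-degenerate labels), per-class
(C-) and overall/pooled (O-) precision, recall and F1 at a fixed decision
threshold, and non-interpolated average precision per label plus its mean
(mAP). Computations delegate to scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = ["EvalResult", "roc_auc", "cfo_metrics", "average_precision", "evaluate_scores"]


@dataclass
class EvalResult:
    auc_per_label: np.ndarray
    auc_macro: float
    cp: float
    cr: float
    cf1: float
    op: float
    or_: float
    of1: float
    ap_per_label: np.ndarray
    map: float
    threshold: float

    def as_dict(self) -> dict:
        return {
            "AUC": self.auc_macro, "C-P": self.cp, "C-R": self.cr, "C-F1": self.cf1,
            "O-P": self.op, "O-R": self.or_, "O-F1": self.of1, "mAP": self.map,
            "threshold": self.threshold,
        }


def _validate(scores, truths):
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths)
    if scores.shape != truths.shape or scores.ndim != 2:
        raise ValueError("scores and truths must both be (n_graphs, C)")
    return scores, truths


def _nondegenerate(truths) -> np.ndarray:
    pos = truths.sum(axis=0)
    return (pos > 0) & (pos < truths.shape[0])


def roc_auc(scores, truths):
    """Per-label ROC-AUC (midrank ties) and its macro average.

    Labels with no positives or no negatives are excluded from the macro
    average (their per-label entry is NaN); all-degenerate input is an error.
    """
    scores, truths = _validate(scores, truths)
    C = truths.shape[1]
    ok = _nondegenerate(truths)
    if not ok.any():
        raise ValueError("every label is degenerate (all-positive or all-negative)")
    if not ok.all():
        logger.info("roc_auc: excluding %d degenerate label(s) from macro", (~ok).sum())
    per = np.full(C, np.nan)
    for c in np.where(ok)[0]:
        per[c] = roc_auc_score(truths[:, c], scores[:, c])
    return per, float(np.nanmean(per))


def cfo_metrics(probabilities, truths, threshold: float = 0.5):
    """Per-class (macro) and overall (micro) precision / recall / F1.

    Predictions are probability >= threshold. Labels with a zero denominator
    contribute 0 to the macro averages; overall metrics pool the confusion
    counts over every (graph, label) slot.
    """
    probabilities, truths = _validate(probabilities, truths)
    pred = (probabilities >= threshold).astype(np.int64)
    tp = ((pred == 1) & (truths == 1)).sum(axis=0).astype(np.float64)
    fp = ((pred == 1) & (truths == 0)).sum(axis=0).astype(np.float64)
    fn = ((pred == 0) & (truths == 1)).sum(axis=0).astype(np.float64)

    def safe(num, den, what):
        zero = den == 0
        if np.any(zero):
            logger.info("cfo_metrics: %d label(s) with zero %s denominator contribute 0",
                        int(zero.sum()), what)
        return np.where(zero, 0.0, num / np.where(zero, 1.0, den))

    p = safe(tp, tp + fp, "precision")
    r = safe(tp, tp + fn, "recall")
    f1 = np.where(p + r > 0, 2 * p * r / np.where(p + r > 0, p + r, 1.0), 0.0)
    TP, FP, FN = tp.sum(), fp.sum(), fn.sum()
    op = TP / (TP + FP) if TP + FP > 0 else 0.0
    or_ = TP / (TP + FN) if TP + FN > 0 else 0.0
    of1 = 2 * op * or_ / (op + or_) if op + or_ > 0 else 0.0
    return {"C-P": float(p.mean()), "C-R": float(r.mean()), "C-F1": float(f1.mean()),
            "O-P": float(op), "O-R": float(or_), "O-F1": float(of1)}


def average_precision(scores, truths):
    """Non-interpolated per-label average precision and its mean (mAP)."""
    scores, truths = _validate(scores, truths)
    C = truths.shape[1]
    per = np.full(C, np.nan)
    for c in range(C):
        if truths[:, c].sum() > 0:
            per[c] = average_precision_score(truths[:, c], scores[:, c])
    if np.all(np.isnan(per)):
        raise ValueError("no label has a positive example")
    return per, float(np.nanmean(per))


def evaluate_scores(scores, truths, threshold: float = 0.5) -> EvalResult:
    """All metrics in one pass over (n_graphs, C) score and truth matrices."""
    auc_per, auc_macro = roc_auc(scores, truths)
    cfo = cfo_metrics(scores, truths, threshold=threshold)
    ap_per, map_ = average_precision(scores, truths)
    return EvalResult(
        auc_per_label=auc_per, auc_macro=auc_macro,
        cp=cfo["C-P"], cr=cfo["C-R"], cf1=cfo["C-F1"],
        op=cfo["O-P"], or_=cfo["O-R"], of1=cfo["O-F1"],
        ap_per_label=ap_per, map=map_, threshold=threshold,
    )
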