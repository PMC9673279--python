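"""Evaluation metrics for the out-of-fold ensemble predictions.

Per-class precision/recall are reported separately for the diseased
(class 1) and control (class 0) groups, and the final F1 is the macro
average of the two per-class F1 scores.  The classification threshold on
the averaged out-of-fold probability is 0.5, with probability >= 0.5
mapped to diseased.
"""

from __future__ import annotations

import numpy as np

from .stats import mann_whitney_auc_matrix

METRIC_NAMES = (
    "auc",
    "accuracy",
    "precision_class1",
    "precision_class0",
    "recall_class1",
    "recall_class0",
    "macro_f1",
)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(probabilities, labels, threshold: float = 0.5) -> dict[str, float]:
    """AUC plus thresholded confusion-matrix metrics.

    AUC is the tie-corrected rank statistic of the probabilities against
    the labels; accuracy, per-class precision/recall and macro-F1 come
    from the confusion matrix at ``threshold`` (>= maps to class 1).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined with a single class")
    auc = float(mann_whitney_auc_matrix(p[:, None], y)[0])
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    precision1 = _safe_div(tp, tp + fp)
    precision0 = _safe_div(tn, tn + fn)
    recall1 = _safe_div(tp, tp + fn)
    recall0 = _safe_div(tn, tn + fp)
    f1_1 = _safe_div(2 * precision1 * recall1, precision1 + recall1)
    f1_0 = _safe_div(2 * precision0 * recall0, precision0 + recall0)
    return {
        "auc": auc,
        "accuracy": (tp + tn) / len(y),
        "precision_class1": precision1,
        "precision_class0": precision0,
        "recall_class1": recall1,
        "recall_class0": recall0,
        "macro_f1": 0.5 * (f1_1 + f1_0),
    }


def interpret_auc(auc: float) -> str:
    """Discriminative-ability band of an AUC value.

    Bands: > 0.7 fair, > 0.8 good, > 0.9 very good; at or below 0.7 the
    test is labelled below-fair.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    if auc > 0.9:
        return "very good"
    if auc > 0.8:
        return "good"
    if auc > 0.7:
        return "fair"
    return "below-fair"
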