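"""Bag- and instance-level evaluation metrics.

ROC AUC uses the rank statistic with tie-averaging (equivalent to the
Mann-Whitney U); PR AUC is average precision (precision-weighted recall
steps).  Both are delegated to scikit-learn behind this surface and are
checked against an exhaustive pairwise oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class EvalResult:
    level: str                 # "bag" or "instance"
    roc_auc: float
    pr_auc: float
    precision: float
    recall: float
    f1: float
    threshold: float
    n_evaluated: int
    coverage_filter: int | None = None
    no_predicted_positives: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def roc_pr(scores, labels) -> tuple[float, float]:
    """(ROC AUC, PR AUC); raises on single-class label vectors."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("undefined AUC: labels contain a single class")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def prf_at(scores, labels, threshold: float = 0.5
           ) -> tuple[float, float, float, bool]:
    """Precision, recall, F1 at a score threshold.

    With no predicted positives, precision is undefined and reported as 0
    with a flag (the fourth return value).  F1 is 0 when precision + recall
    is 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1, undefined


def top_n_precision(scores, labels, n: int, ids=None) -> float:
    """Fraction of true positives among the n highest-scoring items.

    Ties are broken by stable id order, so the result is deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if n > s.shape[0]:
        raise ValueError(f"n={n} exceeds the {s.shape[0]} scored items")
    if ids is None:
        ids = np.arange(s.shape[0])
    order = sorted(range(s.shape[0]), key=lambda i: (-s[i], ids[i]))
    top = order[:n]
    return float(np.mean(y[top]))


def evaluate(scores, labels, level: str = "bag", threshold: float = 0.5,
             coverage_filter: int | None = None) -> EvalResult:
    """Bundle ROC/PR AUC and thresholded metrics into one report."""
    roc, pr = roc_pr(scores, labels)
    precision, recall, f1, undefined = prf_at(scores, labels, threshold)
    return EvalResult(level, roc, pr, precision, recall, f1, threshold,
                      n_evaluated=len(list(labels)),
                      coverage_filter=coverage_filter,
                      no_predicted_positives=undefined)
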