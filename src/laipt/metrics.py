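"""Binary classification metrics in two algebraically equivalent formulations.

The standard formulation works from the confusion matrix (TP, TN, FP, FN).
The Chou formulation works from per-class totals and per-class
misclassification counts (N+, N-, N-+, N+-), which reads more naturally for
site-prediction problems: N-+ is the number of true sites the model missed
and N+- the number of non-sites it called.  Both routes are implemented
independently; their equivalence under the mapping

    TP = N+ - N-+,  TN = N- - N+-,  FP = N+-,  FN = N-+

is enforced by the property-test suite, not assumed by the code.

Also provides ROC / precision-recall curves (threshold sweeps with
Mann-Whitney tie handling) and seeded stratified k-fold cross-validation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ROCCurve",
    "confusion",
    "metrics_standard",
    "metrics_chou",
    "roc_auc",
    "precision_recall",
    "stratified_kfold_indices",
    "kfold_cv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts with the per-class (Chou) view as properties."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def p(self) -> int:
        """Number of positive samples."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Number of negative samples."""
        return self.tn + self.fp

    # Chou view -----------------------------------------------------------
    @property
    def n_plus(self) -> int:
        return self.p

    @property
    def n_minus(self) -> int:
        return self.n

    @property
    def n_minus_plus(self) -> int:
        """Misclassified positives (missed sites)."""
        return self.fn

    @property
    def n_plus_minus(self) -> int:
        """Misclassified negatives (false calls)."""
        return self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    mcc: float
    auc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


@dataclass(frozen=True)
class ROCCurve:
    """ROC points from a threshold sweep, sorted by FPR, (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Tally the four outcomes of binary classification.

    ``labels`` and ``predictions`` are 0/1 arrays of equal length.
    """
    y = np.asarray(labels).astype(int)
    yhat = np.asarray(predictions).astype(int)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {yhat.shape} predictions")
    if not (np.isin(y, (0, 1)).all() and np.isin(yhat, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics_standard(c: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Sn, Sp, Acc, F1 and MCC from confusion-matrix counts.

    Requires both classes present.  The MCC denominator can vanish when the
    classifier predicts a single class; that case returns MCC = 0 (no
    correlation), the usual convention.
    """
    if c.p == 0:
        raise ValueError("no positive samples: sensitivity undefined")
    if c.n == 0:
        raise ValueError("no negative samples: specificity undefined")
    sn = c.tp / c.p
    sp = c.tn / c.n
    acc = (c.tp + c.tn) / (c.p + c.n)
    f1 = 2 * c.tp / (2 * c.tp + c.fn + c.fp) if (2 * c.tp + c.fn + c.fp) > 0 else 0.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricsReport(sensitivity=sn, specificity=sp, accuracy=acc, f1=f1, mcc=mcc, auc=auc)


def metrics_chou(
    n_plus: int,
    n_minus: int,
    n_minus_plus: int,
    n_plus_minus: int,
    auc: float | None = None,
) -> MetricsReport:
    """Sn, Sp, Acc, F1 and MCC from per-class totals and misclassifications.

    ``n_plus`` / ``n_minus`` are the class sizes; ``n_minus_plus`` counts
    positives classified negative and ``n_plus_minus`` negatives classified
    positive.  Computed directly in this parameterization:

        Sn  = 1 - N-+/N+
        Sp  = 1 - N+-/N-
        Acc = 1 - (N-+ + N+-)/(N+ + N-)
        F1  = 2(N+ - N-+) / (2N+ - N-+ + N+-)
        MCC = (1 - (N-+/N+ + N+-/N-))
              / sqrt((1 + (N+- - N-+)/N+)(1 + (N-+ - N+-)/N-))
    """
    if n_plus <= 0 or n_minus <= 0:
        raise ValueError("both class totals must be positive")
    if not (0 <= n_minus_plus <= n_plus):
        raise ValueError("misclassified positives must lie in [0, N+]")
    if not (0 <= n_plus_minus <= n_minus):
        raise ValueError("misclassified negatives must lie in [0, N-]")

    sn = 1.0 - n_minus_plus / n_plus
    sp = 1.0 - n_plus_minus / n_minus
    acc = 1.0 - (n_minus_plus + n_plus_minus) / (n_plus + n_minus)
    f1_den = 2 * n_plus - n_minus_plus + n_plus_minus
    f1 = 2 * (n_plus - n_minus_plus) / f1_den if f1_den > 0 else 0.0
    num = 1.0 - (n_minus_plus / n_plus + n_plus_minus / n_minus)
    d1 = 1.0 + (n_plus_minus - n_minus_plus) / n_plus
    d2 = 1.0 + (n_minus_plus - n_plus_minus) / n_minus
    prod = d1 * d2
    mcc = 0.0 if prod <= 0 else num / math.sqrt(prod)
    return MetricsReport(sensitivity=sn, specificity=sp, accuracy=acc, f1=f1, mcc=mcc, auc=auc)


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    return s, y


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve and AUC by threshold sweep over the unique scores.

    AUC equals the Mann-Whitney statistic: the fraction of
    (positive, negative) pairs ranked correctly, with ties credited 0.5 —
    identical to the trapezoidal area under the swept curve.
    """
    s, y = _validate_scores_labels(scores, labels)
    npos = int((y == 1).sum())
    nneg = int((y == 0).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("ROC requires both classes present")

    # sweep thresholds from +inf down through each unique score
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.where(np.diff(s_sorted) != 0)[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted == 1)[distinct]
    fps = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tps / npos]
    fpr = np.r_[0.0, fps / nneg]

    ranks = rankdata(s)  # average ranks give the 0.5 tie credit
    auc = (ranks[y == 1].sum() - npos * (npos + 1) / 2) / (npos * nneg)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(auc))


def precision_recall(scores: Sequence[float], labels: Sequence[int]) -> list[tuple[float, float]]:
    """(recall, precision) pairs from a descending threshold sweep."""
    s, y = _validate_scores_labels(scores, labels)
    npos = int((y == 1).sum())
    if npos == 0:
        raise ValueError("precision-recall requires at least one positive")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.where(np.diff(s_sorted) != 0)[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted == 1)[distinct]
    called = distinct + 1
    recall = tps / npos
    precision = tps / called
    return list(zip(recall.tolist(), precision.tolist()))


def stratified_kfold_indices(
    labels: Sequence[int], k: int, seed: int
) -> list[np.ndarray]:
    """Seeded stratified fold assignment; returns k test-index arrays.

    Per-fold class counts differ from an even split by at most one sample.
    """
    y = np.asarray(labels).astype(int)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(f"class {cls} has {idx.size} members, fewer than k={k}")
        rng.shuffle(idx)
        for fold, chunk in zip(folds, np.array_split(idx, k)):
            fold.extend(chunk.tolist())
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def kfold_cv(
    features: np.ndarray,
    labels: Sequence[int],
    k: int,
    pipeline: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    seed: int,
) -> tuple[list[MetricsReport], ROCCurve]:
    """Stratified k-fold cross-validation of an arbitrary scoring pipeline.

    ``pipeline(X_train, y_train, X_test) -> scores`` returns a continuous
    score per test sample; labels are called at threshold 0.5.  Returns one
    report per fold plus the ROC pooled over all held-out scores.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    folds = stratified_kfold_indices(y, k, seed)
    reports: list[MetricsReport] = []
    pooled_scores = np.empty(y.size, dtype=float)
    for test_idx in folds:
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        scores = np.asarray(
            pipeline(X[train_mask], y[train_mask], X[test_idx]), dtype=float
        )
        pooled_scores[test_idx] = scores
        c = confusion(y[test_idx], (scores >= 0.5).astype(int))
        fold_auc = roc_auc(scores, y[test_idx]).auc
        reports.append(metrics_standard(c, auc=fold_auc))
    pooled = roc_auc(pooled_scores, y)
    return reports, pooled
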