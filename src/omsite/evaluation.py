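"""Confusion-matrix metrics and evaluation protocols.

Metrics follow the standard binary-classification system: sensitivity
Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/n and the Matthews correlation coefficient

    MCC = (TN*TP - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)),

with the usual degenerate conventions: MCC = 0 when any factor of the
denominator vanishes, Sn reported as missing (None, not 0) when the
evaluated set contains no positives.

Two protocols are provided: a stratified 80:20 independent test split
and stratified k-fold cross-validation (default k = 5).  The feature
scaler is refitted inside every training partition (``models.train``
does this structurally), so no statistics leak into a test fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_auc_score, roc_curve

from . import models as _models
from .sequence_io import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sn/Sp/Acc/MCC (plus optional AUC); Sn is None when undefined."""

    sn: Optional[float]
    sp: Optional[float]
    acc: float
    mcc: float
    auc: Optional[float] = None


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """TP/TN/FP/FN with positive class = 1."""
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValidationError("labels and predictions must be equal-length 1-D")
    if y.size < 1:
        raise ValidationError("need at least one row")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def metrics(counts: ConfusionCounts, auc: Optional[float] = None) -> MetricSet:
    """Sn, Sp, Acc, MCC from confusion counts (degenerate rules above)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValidationError("empty confusion matrix")
    sn = tp / (tp + fn) if (tp + fn) > 0 else None
    sp = tn / (tn + fp) if (tn + fp) > 0 else None
    acc = (tp + tn) / counts.total
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = 0.0 if denom == 0 else (tn * tp - fp * fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc, auc=auc)


def roc(labels: Sequence[int], scores: Sequence[float]):
    """ROC curve and trapezoidal AUC over the continuous scores.

    Returns (auc, fpr, tpr).  Requires both classes present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return float(_sk_auc(fpr, tpr)), fpr, tpr


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def split_80_20(
    table: pd.DataFrame, labels, seed: int = 0, test_fraction: float = 0.2
):
    """Stratified independent-test split.

    The test partition takes round(test_fraction * class size) rows of
    each class (remainder stays in training); deterministic under seed;
    train and test are disjoint and exhaustive.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) < 5:
        raise ValidationError("need at least 5 rows to split")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if members.size < 2:
            raise ValidationError(f"class {cls} has fewer than 2 members")
        n_test = int(round(test_fraction * members.size))
        test_idx.extend(rng.permutation(members)[:n_test].tolist())
    test_mask = np.zeros(len(y), dtype=bool)
    test_mask[test_idx] = True
    train_table = table.iloc[~test_mask]
    test_table = table.iloc[test_mask]
    return train_table, y[~test_mask], test_table, y[test_mask]


def stratified_fold_indices(labels, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Test-fold index arrays for stratified k-fold.

    Shuffled per-class index blocks are dealt round-robin to the k
    folds with a single global counter, so overall fold sizes are as
    balanced as possible (ceil/floor of n/k) AND per-class counts
    differ by at most one across folds.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValidationError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValidationError(f"every class needs at least k={k} members")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0
    for cls in classes:
        members = rng.permutation(np.flatnonzero(y == cls))
        for idx in members:
            folds[cursor % k].append(int(idx))
            cursor += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def independent_test(
    table: pd.DataFrame, labels, spec: "_models.ModelSpec", seed: int = 0
) -> MetricSet:
    """Train on the stratified 80% partition, evaluate on the held-out 20%."""
    train_t, train_y, test_t, test_y = split_80_20(table, labels, seed=seed)
    model = _models.train(train_t, train_y, spec)
    scores, calls = _models.predict(model, test_t)
    return metrics(confusion(test_y, calls), auc=roc_auc(test_y, scores))


def kfold_cv(
    table: pd.DataFrame, labels, spec: "_models.ModelSpec", k: int = 5, seed: int = 0
) -> tuple[list[MetricSet], MetricSet]:
    """Stratified k-fold cross-validation; scaler refitted per fold.

    Returns the per-fold metric sets and their unweighted mean (AUC
    averaged likewise; Sn/Sp averaged over folds where defined).
    """
    y = np.asarray(labels, dtype=int)
    fold_metrics: list[MetricSet] = []
    for test_idx in stratified_fold_indices(y, k=k, seed=seed):
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        model = _models.train(table.iloc[~mask], y[~mask], spec)
        scores, calls = _models.predict(model, table.iloc[mask])
        fold_metrics.append(
            metrics(confusion(y[mask], calls), auc=roc_auc(y[mask], scores))
        )

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    mean = MetricSet(
        sn=_mean([m.sn for m in fold_metrics]),
        sp=_mean([m.sp for m in fold_metrics]),
        acc=float(np.mean([m.acc for m in fold_metrics])),
        mcc=float(np.mean([m.mcc for m in fold_metrics])),
        auc=_mean([m.auc for m in fold_metrics]),
    )
    return fold_metrics, mean


def report(
    results: dict[tuple[str, str], MetricSet], protocol: str
) -> pd.DataFrame:
    """Wide table keyed by (dataset, model): Acc/Sp/Sn/MCC.

    Full-precision values are kept in the acc/sp/sn/mcc columns; the
    *_2dp columns carry the 2-decimal rendering used in summary tables.
    """
    if not results:
        raise ValidationError("no results to report")
    if not protocol:
        raise ValidationError("protocol tag must be non-empty")
    rows = []
    for (dataset, model_name), m in results.items():
        row = {
            "dataset": dataset,
            "model": model_name,
            "protocol": protocol,
            "acc": m.acc,
            "sp": m.sp,
            "sn": m.sn,
            "mcc": m.mcc,
            "auc": m.auc,
        }
        for key in ("acc", "sp", "sn", "mcc"):
            val = row[key]
            row[f"{key}_2dp"] = "" if val is None else f"{val:.2f}"
        rows.append(row)
    return pd.DataFrame(rows)
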