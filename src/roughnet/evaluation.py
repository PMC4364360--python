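"""Classifier evaluation: confusion matrix, derived metrics, ROC/AUC, splits.

The five reported metrics are the standard ones computed from the 2×2
confusion matrix of a binary classifier:

    accuracy    = (TP + TN) / (TP + TN + FP + FN) × 100%
    sensitivity = TP / (TP + FN) × 100%
    specificity = TN / (TN + FP) × 100%
    TPR         = TP / (TP + FN)
    FPR         = FP / (FP + TN)

A metric whose denominator is zero is reported as undefined (``None``), never
as 0.  The ROC curve sweeps the decision threshold over the distinct scores
(ties step simultaneously) and the AUC is the trapezoidal area, which equals
the Mann–Whitney probability of ranking a positive above a negative with ties
counted half.

Splitting follows the random-division convention: the training share of an
N-object universe is round-half-up(fraction · N) objects of a seeded shuffle;
k-fold partitioning deals shuffled objects into folds of size ⌊N/k⌋ or one
more.  Stratified splitting is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Derived metrics; percentages in [0, 100], rates in [0, 1], None = undefined."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    tpr: float | None
    fpr: float | None
    auc: float | None = None

    def rounded(
        self,
        percent_dp: int = 2,
        tpr_dp: int = 2,
        fpr_dp: int = 3,
        auc_dp: int = 4,
    ) -> dict:
        """Report-style rounding (percentages to 2 dp, TPR 2 dp, FPR 3 dp, AUC 4 dp)."""

        def r(v: float | None, dp: int) -> float | None:
            return None if v is None else round(v, dp)

        return {
            "accuracy": r(self.accuracy, percent_dp),
            "sensitivity": r(self.sensitivity, percent_dp),
            "specificity": r(self.specificity, percent_dp),
            "tpr": r(self.tpr, tpr_dp),
            "fpr": r(self.fpr, fpr_dp),
            "auc": r(self.auc, auc_dp),
        }


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    k_folds: int = 10
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[tuple[float, float], ...]  # (fpr, tpr), (0,0) .. (1,1)
    auc: float


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------


def confusion(
    y_true: Sequence[object], y_pred: Sequence[object], positive_label: object
) -> ConfusionMatrix:
    """2×2 tally with the stated positive label; everything else is negative."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal lengths")
    labels = set(y_true) | set(y_pred)
    if len(labels) > 2:
        raise ValueError(f"binary evaluation requires at most 2 labels, got {sorted(map(str, labels))}")
    tp = fn = fp = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricSet:
    """Accuracy/sensitivity/specificity (percent) and TPR/FPR (fractions)."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    return MetricSet(
        accuracy=(cm.tp + cm.tn) / cm.total * 100.0,
        sensitivity=None if sens is None else sens * 100.0,
        specificity=None if spec is None else spec * 100.0,
        tpr=sens,
        fpr=ratio(cm.fp, cm.fp + cm.tn),
        auc=auc,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(
    scores: Sequence[float], y_true: Sequence[object], positive_label: object
) -> ROCCurve:
    """ROC curve by threshold sweep over distinct scores, trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray([t == positive_label for t in y_true])
    n_pos = int(truth.sum())
    n_neg = int(len(truth) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]

    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        # tied scores cross the threshold together: one simultaneous step
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            tp += int(sorted_truth[j])
            fp += int(not sorted_truth[j])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return ROCCurve(points=tuple(points), auc=float(auc))


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split(
    ids: Sequence[str], spec: SplitSpec, labels: Sequence[object] | None = None
) -> tuple[list[str], list[str]]:
    """Seeded random train/test split; train size = round-half-up(fraction·N).

    With ``spec.stratified`` (requires ``labels``), each class contributes its
    proportional share of the training set, largest-remainder rounded so the
    total still matches.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 objects to split")
    rng = np.random.default_rng(spec.seed)
    n_train = _round_half_up(spec.train_fraction * n)
    n_train = min(max(n_train, 1), n - 1)

    if not spec.stratified:
        perm = rng.permutation(n)
        train = [ids[i] for i in perm[:n_train]]
        test = [ids[i] for i in perm[n_train:]]
        return train, test

    if labels is None:
        raise ValueError("stratified split requires labels")
    by_class: dict[object, list[str]] = {}
    for obj, lab in zip(ids, labels):
        by_class.setdefault(lab, []).append(obj)
    quotas = {c: spec.train_fraction * len(members) for c, members in by_class.items()}
    take = {c: int(math.floor(q)) for c, q in quotas.items()}
    shortfall = n_train - sum(take.values())
    for c in sorted(by_class, key=lambda c: quotas[c] - take[c], reverse=True):
        if shortfall <= 0:
            break
        take[c] += 1
        shortfall -= 1
    train, test = [], []
    for c, members in by_class.items():
        perm = rng.permutation(len(members))
        chosen = set(perm[: take[c]])
        for i, obj in enumerate(members):
            (train if i in chosen else test).append(obj)
    return train, test


def kfold(ids: Sequence[str], spec: SplitSpec) -> list[list[str]]:
    """Seeded k disjoint folds covering all ids, sized ⌊N/k⌋ or one more."""
    ids = list(ids)
    n = len(ids)
    k = spec.k_folds
    if n < k:
        raise ValueError(f"need at least k={k} objects, got {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    folds: list[list[str]] = []
    start = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        folds.append([ids[i] for i in perm[start : start + size]])
        start += size
    return folds
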