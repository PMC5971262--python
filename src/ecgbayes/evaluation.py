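"""Confusion matrices, per-class Se/PPV/F1, splits, cross-validation and
model selection.

Metric definitions (one-vs-rest per class): sensitivity Se = TP/(TP+FN),
positive predictive value PPV = TP/(TP+FP), F1 = 2*Se*PPV/(Se+PPV).  A zero
denominator yields 0 for the affected metric, so all three are total
functions of the confusion matrix.

Confusion-matrix convention: rows are the reference (true) class, columns
the predicted class.

The experiment protocol: a stratified 70/15/15 train/validation/test split;
stratified 10-fold cross-validation on train+validation to pick the
classifier with the highest mean-over-classes of mean-over-folds F1; the
winner is refit on train+validation and scored once on the held-out test
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureDataset
from .models import ClassifierModel, fit, predict

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "SplitPlan",
    "CVPlan",
    "confusion",
    "class_metrics",
    "metrics_report",
    "make_split",
    "make_cv_plan",
    "cross_validate",
    "select_model",
    "final_evaluation",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        K = len(self.class_order)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be K x K for K classes")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order,
                            columns=self.class_order)


@dataclass
class MetricsReport:
    per_class: dict[str, tuple[float, float, float]]  # label -> (Se, PPV, F1)
    macro_mean_f1: float
    confusion: ConfusionMatrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {lab: dict(zip(("Se", "PPV", "F1"), vals))
             for lab, vals in self.per_class.items()}
        ).T


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


@dataclass
class CVPlan:
    fold_of_row: np.ndarray  # fold id per row, 0..n_folds-1
    n_folds: int
    seed: int

    def folds(self):
        for f in range(self.n_folds):
            test = np.flatnonzero(self.fold_of_row == f)
            train = np.flatnonzero(self.fold_of_row != f)
            yield train, test


def confusion(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=object).astype(str)
    p = np.asarray(predicted_labels, dtype=object).astype(str)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    K = len(class_order)
    counts = np.zeros((K, K), dtype=np.int64)
    for ti, pi in zip(t, p):
        if ti not in index or pi not in index:
            raise ValueError(f"label {ti!r}/{pi!r} not in class order {class_order}")
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(counts=counts, class_order=list(class_order))


def class_metrics(cm: ConfusionMatrix, cls: str) -> tuple[float, float, float]:
    """One-vs-rest (Se, PPV, F1) for one class; zero-denominator -> 0."""
    i = cm.class_order.index(cls)
    tp = cm.counts[i, i]
    fn = cm.counts[i, :].sum() - tp
    fp = cm.counts[:, i].sum() - tp
    se = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * se * ppv / (se + ppv) if se + ppv else 0.0
    return float(se), float(ppv), float(f1)


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    per_class = {c: class_metrics(cm, c) for c in cm.class_order}
    macro = float(np.mean([v[2] for v in per_class.values()]))
    return MetricsReport(per_class=per_class, macro_mean_f1=macro, confusion=cm)


def _stratified_shuffle(labels: np.ndarray, seed: int):
    rng = np.random.default_rng(seed)
    labels = labels.astype(str)
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        yield cls, idx


def make_split(
    data: FeatureDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitPlan:
    """Stratified train/validation/test split; remainder rows go to train."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    labels = data.labels.astype(str)
    train, val, test = [], [], []
    for cls, idx in _stratified_shuffle(labels, seed):
        n_c = idx.shape[0]
        if n_c < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples; cannot split")
        n_val = int(np.floor(fractions[1] * n_c))
        n_test = int(np.floor(fractions[2] * n_c))
        test.append(idx[:n_test])
        val.append(idx[n_test : n_test + n_val])
        train.append(idx[n_test + n_val :])
    return SplitPlan(
        train_idx=np.sort(np.concatenate(train)),
        val_idx=np.sort(np.concatenate(val)),
        test_idx=np.sort(np.concatenate(test)),
        seed=seed,
    )


def make_cv_plan(data: FeatureDataset, n_folds: int = 10, seed: int = 0) -> CVPlan:
    """Stratified fold assignment: within each class, fold sizes differ by <= 1."""
    labels = data.labels.astype(str)
    fold_of_row = np.full(labels.shape[0], -1, dtype=int)
    for cls, idx in _stratified_shuffle(labels, seed):
        if idx.shape[0] < n_folds:
            raise ValueError(
                f"class {cls!r} has {idx.shape[0]} samples, fewer than "
                f"{n_folds} folds")
        fold_of_row[idx] = np.arange(idx.shape[0]) % n_folds
    return CVPlan(fold_of_row=fold_of_row, n_folds=n_folds, seed=seed)


def cross_validate(kind: str, data: FeatureDataset, cv: CVPlan):
    """Fit on 9 folds / score the held-out fold, for every fold.

    Returns (list of per-fold MetricsReport, dict of per-class fold-mean F1).
    """
    reports: list[MetricsReport] = []
    classes = sorted(set(data.labels.astype(str).tolist()))
    for train_idx, test_idx in cv.folds():
        train, test = data.subset(train_idx), data.subset(test_idx)
        train_classes = set(train.labels.astype(str).tolist())
        if train_classes != set(classes):
            raise ValueError("a class is missing from a CV training part")
        model = fit(kind, train)
        pred = predict(model, test.matrix)
        cm = confusion(test.labels, pred, model.classes)
        reports.append(metrics_report(cm))
    fold_mean_f1 = {
        c: float(np.mean([r.per_class[c][2] for r in reports])) for c in classes
    }
    return reports, fold_mean_f1


def select_model(candidates, data: FeatureDataset, cv: CVPlan):
    """Pick the candidate with the highest mean-over-classes fold-mean F1.

    Returns (winning kind, {kind: mean-of-means F1}).  Ties break by
    candidate list order.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    scores: dict[str, float] = {}
    for kind in candidates:
        _, fold_mean_f1 = cross_validate(kind, data, cv)
        scores[kind] = float(np.mean(list(fold_mean_f1.values())))
    best = max(candidates, key=lambda k: scores[k])  # max is stable: first wins
    return best, scores


def final_evaluation(kind: str, split: SplitPlan, data: FeatureDataset) -> MetricsReport:
    """Refit on train+validation, score the untouched test set."""
    fit_idx = np.concatenate([split.train_idx, split.val_idx])
    model = fit(kind, data.subset(fit_idx))
    test = data.subset(split.test_idx)
    pred = predict(model, test.matrix)
    cm = confusion(test.labels, pred, model.classes)
    return metrics_report(cm)
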