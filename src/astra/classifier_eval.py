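"""Maximum-margin classification of miRNA targets and its evaluation.

A soft-margin linear-kernel classifier (regularization constant 1) is
assessed by stratified ten-fold cross-validation with pooled out-of-fold
confusion counts, and a model trained on the full gold set is applied to
external *MIRNA*-gene feature sets grouped by evolutionary age.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .feature_builder import FEATURE_SUBSETS

logger = logging.getLogger("astra")

DEFAULT_FOLDS = 10
DEFAULT_C = 1.0


@dataclass
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


@dataclass
class CVMetrics:
    """Accuracy, sensitivity, specificity and precision from pooled counts.

    Precision is NaN when no positive prediction was made (division by
    zero); the NaN is reported as-is, never averaged away.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    confusion: ConfusionCounts
    folds: int = 0
    seed: int = 0
    feature_subset: tuple[str, ...] = ()


def metrics_from_confusion(c: ConfusionCounts, folds: int = 0, seed: int = 0,
                           feature_subset: tuple[str, ...] = ()) -> CVMetrics:
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    pos, neg = c.tp + c.fn, c.tn + c.fp
    return CVMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=c.tp / pos if pos else math.nan,
        specificity=c.tn / neg if neg else math.nan,
        precision=c.tp / (c.tp + c.fp) if c.tp + c.fp else math.nan,
        confusion=c, folds=folds, seed=seed, feature_subset=feature_subset,
    )


def _select_columns(X: pd.DataFrame,
                    feature_subset: Sequence[str] | None) -> pd.DataFrame:
    if not feature_subset:
        return X
    cols: list[str] = []
    for name in feature_subset:
        if name not in FEATURE_SUBSETS:
            raise ValueError(f"unknown feature subset {name!r}")
        cols += [c for c in FEATURE_SUBSETS[name] if c in X.columns]
    if not cols:
        raise ValueError("feature subset selects zero columns")
    return X[cols]


@dataclass
class TrainedModel:
    """A fitted linear classifier with its training column layout."""

    svc: SVC
    columns: list[str]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"feature layout mismatch, missing {missing}")
        return self.svc.predict(X[self.columns].to_numpy(dtype=float))


def train_model(X: pd.DataFrame, y: Sequence[int],
                feature_subset: Sequence[str] | None = None,
                C: float = DEFAULT_C) -> TrainedModel:
    Xs = _select_columns(X, feature_subset)
    svc = SVC(kernel="linear", C=C)
    svc.fit(Xs.to_numpy(dtype=float), np.asarray(y))
    return TrainedModel(svc, list(Xs.columns))


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[int],
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    feature_subset: Sequence[str] | None = None,
    C: float = DEFAULT_C,
) -> CVMetrics:
    """Stratified k-fold cross-validation with pooled out-of-fold counts.

    Folds come from a seeded shuffling stratified splitter; should a fold
    still end up single-class in training (possible only for tiny classes),
    the data is refolded with the next seed, logged. Metrics are computed
    once from the confusion counts pooled over all held-out predictions.
    """
    y = np.asarray(y)
    if len(y) < k:
        raise ValueError("need at least k samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Xs = _select_columns(X, feature_subset).to_numpy(dtype=float)
    if Xs.shape[1] == 0:
        raise ValueError("zero feature columns")

    attempt_seed = seed
    for _ in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=attempt_seed)
        folds = list(skf.split(Xs, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
        logger.warning("single-class fold with seed %d; refolding",
                       attempt_seed)
        attempt_seed += 1
    else:
        raise ValueError("could not build two-class folds")

    tp = fp = tn = fn = 0
    for train_idx, test_idx in folds:
        svc = SVC(kernel="linear", C=C)
        svc.fit(Xs[train_idx], y[train_idx])
        pred = svc.predict(Xs[test_idx])
        truth = y[test_idx]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fp += int(np.sum((pred == 1) & (truth == -1)))
        tn += int(np.sum((pred == -1) & (truth == -1)))
        fn += int(np.sum((pred == -1) & (truth == 1)))
    return metrics_from_confusion(
        ConfusionCounts(tp, fp, tn, fn), folds=k, seed=attempt_seed,
        feature_subset=tuple(feature_subset or ()))


def evaluate_external(
    model: TrainedModel,
    X_ext: pd.DataFrame,
    y_ext: Sequence[int],
    groups: Sequence[str],
) -> pd.DataFrame:
    """Per-group and total prediction accuracy on an external set.

    ``groups`` labels each row (e.g. ``mirna_ancient`` / ``mirna_new``); the
    total row is the count-weighted accuracy over all rows.
    """
    y_ext = np.asarray(y_ext)
    groups = np.asarray(groups)
    pred = model.predict(X_ext)
    rows = []
    for g in sorted(set(groups)):
        mask = groups == g
        rows.append((g, int(mask.sum()),
                     float(np.mean(pred[mask] == y_ext[mask]))))
    rows.append(("total", len(y_ext), float(np.mean(pred == y_ext))))
    return pd.DataFrame(rows, columns=["group", "n", "accuracy"])


def subset_metrics_table(
    X: pd.DataFrame,
    y: Sequence[int],
    subsets: Sequence[tuple[str, ...]] = (
        ("expr", "smrna", "energy"),
        ("smrna", "energy"),
        ("expr", "energy"),
        ("expr", "smrna"),
        ("smrna",),
        ("energy",),
        ("expr",),
    ),
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated metrics for each named feature-subset combination."""
    rows = []
    for subset in subsets:
        m = cross_validate(X, y, k=k, seed=seed, feature_subset=subset)
        rows.append((", ".join(subset), m.accuracy, m.sensitivity,
                     m.precision, m.specificity))
    return pd.DataFrame(rows, columns=[
        "combination", "accuracy", "sensitivity", "precision",
        "specificity"])
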