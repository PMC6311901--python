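"""L1-regularized logistic-regression feature selection.

The model minimises ``||w||_1 + C * sum_i log(1 + exp(-y_i (X_i^T w + c)))``
with labels mapped to {-1, +1} (0 = ribosome-free -> -1). Larger C means a
weaker penalty and more nonzero coefficients, so feature selection reduces
to choosing C: the data are split 80:20 (stratified), the model is fit on
the training part for every C on a grid, and the chosen C is the smallest
one whose held-out accuracy is within ``epsilon`` of the best over the
grid — few features, near-peak accuracy. Five-fold cross-validation
accuracy on the training part is recorded alongside as a diagnostic (and
can be used as the selection signal instead).

The sign of a selected coefficient gives the direction of association
with the ribosome-associated class; |w| ranks importance (features being
on a common [0, 1] scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .pipeline import FeatureMatrix


@dataclass
class LRModel:
    w: np.ndarray
    c: float
    C: float
    feature_names: list[str]
    majority_label: int  # training-majority class, used at decision ties

    @property
    def nonzero(self) -> np.ndarray:
        return np.nonzero(self.w)[0]

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.c

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.decision(X)
        out = np.where(s > 0, 1, 0)
        out[s == 0] = self.majority_label
        return out

    def objective(self, X: np.ndarray, y01: np.ndarray) -> float:
        """Value of the penalised loss this model minimises."""
        ypm = np.where(np.asarray(y01) == 1, 1.0, -1.0)
        z = -ypm * self.decision(X)
        return float(np.abs(self.w).sum() + self.C * np.logaddexp(0.0, z).sum())


def fit_l1_lr(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    seed: int = 0,
    tol: float = 1e-4,
    feature_names: Optional[Sequence[str]] = None,
) -> LRModel:
    """Fit the L1 objective (liblinear); coefficients below 10*tol in
    magnitude are reported as exact zeros."""
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=tol, random_state=seed,
        max_iter=1000,
    )
    clf.fit(X, y)
    w = clf.coef_[0].copy()
    c = float(clf.intercept_[0])
    cut = 10.0 * tol
    w[np.abs(w) < cut] = 0.0
    if abs(c) < cut:
        c = 0.0
    n1 = int((y == 1).sum())
    majority = 1 if n1 * 2 >= len(y) else 0
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    return LRModel(w, c, C, names, majority)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def accuracy(cc: ConfusionCounts) -> float:
    total = cc.TP + cc.TN + cc.FP + cc.FN
    if total == 0:
        raise ValueError("empty confusion counts")
    return (cc.TP + cc.TN) / total


def default_grid(start: float = 0.01, stop: float = 1.0, step: float = 0.001) -> np.ndarray:
    """Inclusive arithmetic grid from start towards stop (never past it)."""
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return np.round(start + step * np.arange(n), 10)


@dataclass
class SweepResult:
    grid: np.ndarray
    nonzero_counts: np.ndarray
    accuracies: np.ndarray  # held-out (20%) accuracy per C
    cv_accuracies: np.ndarray  # 5-fold CV accuracy on the training part
    split_seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    seed: int = 0
    tol: float = 1e-4


def sweep_C(
    m: FeatureMatrix,
    grid: Optional[Sequence[float]] = None,
    split_seed: int = 0,
    cv_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
) -> SweepResult:
    """One stratified 80:20 split, then a fit per C on the grid recording
    held-out accuracy, nonzero count, and training-part CV accuracy."""
    grid = np.asarray(default_grid() if grid is None else list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty C grid")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("C grid must be strictly increasing")
    X = m.X.to_numpy(dtype=float)
    y = m.y
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=0.2, stratify=y, random_state=split_seed
    )
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte, yte = X[test_idx], y[test_idx]
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=split_seed)
    folds = list(skf.split(Xtr, ytr))

    nz, acc, cv_acc = [], [], []
    for C in grid:
        model = fit_l1_lr(Xtr, ytr, C, seed=seed, tol=tol, feature_names=m.feature_names)
        nz.append(len(model.nonzero))
        acc.append(accuracy(confusion(yte, model.predict(Xte))))
        fold_accs = []
        for tr, va in folds:
            fm = fit_l1_lr(Xtr[tr], ytr[tr], C, seed=seed, tol=tol)
            fold_accs.append(accuracy(confusion(ytr[va], fm.predict(Xtr[va]))))
        cv_acc.append(float(np.mean(fold_accs)))

    return SweepResult(
        grid=grid,
        nonzero_counts=np.asarray(nz),
        accuracies=np.asarray(acc),
        cv_accuracies=np.asarray(cv_acc),
        split_seed=split_seed,
        train_idx=train_idx,
        test_idx=test_idx,
        feature_names=m.feature_names,
        X=X,
        y=y,
        seed=seed,
        tol=tol,
    )


def select_C(
    s: SweepResult, epsilon: float = 0.005, select_on: str = "test"
) -> tuple[float, LRModel]:
    """Smallest grid C whose accuracy is within epsilon of the grid maximum;
    the returned model is refit at that C on the training part."""
    curve = {"test": s.accuracies, "cv": s.cv_accuracies}[select_on]
    best = curve.max()
    chosen_idx = int(np.nonzero(curve >= best - epsilon)[0][0])
    chosen_C = float(s.grid[chosen_idx])
    model = fit_l1_lr(
        s.X[s.train_idx], s.y[s.train_idx], chosen_C, seed=s.seed, tol=s.tol,
        feature_names=s.feature_names,
    )
    return chosen_C, model


@dataclass(frozen=True)
class FeatureReport:
    feature: str
    coefficient: float
    sign: str
    rank: int


def report_features(model: LRModel) -> list[FeatureReport]:
    """Nonzero features sorted by |coefficient| descending."""
    idx = sorted(model.nonzero, key=lambda i: -abs(model.w[i]))
    if len(idx) == 0:
        import logging

        logging.getLogger(__name__).warning("all coefficients are zero; empty report")
    return [
        FeatureReport(model.feature_names[i], float(model.w[i]),
                      "+" if model.w[i] > 0 else "-", r + 1)
        for r, i in enumerate(idx)
    ]


def sweep_table(s: SweepResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "C": s.grid,
            "nonzero": s.nonzero_counts,
            "acc_test": s.accuracies,
            "acc_cv": s.cv_accuracies,
        }
    )
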