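"""Hyperparameter tuning: repeated stratified k-fold CV over a (dropout, L2) grid.

The default grids follow the two published calibrations: dropout keep
probability 0.4-0.9 in steps of 0.1 crossed with an L2 constant of either
0.4-1.6 (zebrafish scheme, 42 points) or 0.2-1.2 (human scheme, 36 points)
in steps of 0.2.  Five-fold cross-validation is repeated three times with
fold assignments re-randomized per repeat; the grid point with the highest
mean held-fold accuracy wins, ties resolved toward the less regularized
model (smaller L2, then larger keep probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classifier import ModelSpec, StageScheme, train

ZEBRAFISH_DROPOUT = (0.4, 0.9, 0.1)
ZEBRAFISH_L2 = (0.4, 1.6, 0.2)
HUMAN_L2 = (0.2, 1.2, 0.2)


def _inclusive_range(lo: float, hi: float, step: float) -> list:
    if step <= 0:
        raise ValueError("step must be positive")
    if hi < lo:
        raise ValueError("empty range")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return [round(lo + i * step, 12) for i in range(n)]


@dataclass
class HyperGrid:
    dropout_values: list
    l2_values: list
    folds: int = 5
    repeats: int = 3

    def __post_init__(self) -> None:
        if not self.dropout_values or not self.l2_values:
            raise ValueError("grid must contain at least one point per axis")
        if any(not 0 < d <= 1 for d in self.dropout_values):
            raise ValueError("dropout keep probabilities must be in (0, 1]")
        if any(l < 0 for l in self.l2_values):
            raise ValueError("l2 values must be nonnegative")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def points(self) -> list:
        return [(d, l) for d in self.dropout_values for l in self.l2_values]

    def __len__(self) -> int:
        return len(self.points)


def make_grid(
    dropout_range=ZEBRAFISH_DROPOUT,
    l2_range=ZEBRAFISH_L2,
    folds: int = 5,
    repeats: int = 3,
) -> HyperGrid:
    """Inclusive arithmetic grids from (lo, hi, step) triples."""
    return HyperGrid(
        _inclusive_range(*dropout_range), _inclusive_range(*l2_range), folds, repeats
    )


@dataclass
class CVResult:
    """Mean/SD accuracy per grid point plus the selected optimum."""

    table: pd.DataFrame  # columns: dropout, l2, mean_acc, sd_acc
    best: tuple  # (dropout, l2)
    fold_assignments: list = field(default_factory=list)  # (repeat, fold, test ids)

    def __post_init__(self) -> None:
        accs = self.table["mean_acc"]
        if ((accs < 0) | (accs > 1)).any() or (self.table["sd_acc"] < 0).any():
            raise ValueError("accuracies must be in [0,1] and SDs nonnegative")


def select_best(table: pd.DataFrame) -> tuple:
    """Argmax of mean accuracy; ties -> smaller l2, then larger dropout keep."""
    if table.empty:
        raise ValueError("empty CV table")
    ranked = table.sort_values(
        ["mean_acc", "l2", "dropout"], ascending=[False, True, False], kind="mergesort"
    )
    row = ranked.iloc[0]
    return (float(row["dropout"]), float(row["l2"]))


def cross_validate_grid(
    X: np.ndarray,
    y,
    grid: HyperGrid,
    spec: ModelSpec,
    scheme: StageScheme,
    seed: int = 0,
    cv_epochs: int | None = None,
) -> CVResult:
    """Repeated stratified k-fold accuracy for every (dropout, l2) grid point.

    ``cv_epochs`` optionally trains with a reduced epoch budget during CV
    while leaving the final-fit budget in ``spec`` untouched.  Fold
    assignments are identical across grid points within a (repeat, fold)
    pair, so grid points are compared on the same partitions.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = pd.Series(y).reset_index(drop=True)
    counts = y.value_counts()
    if (counts < grid.folds).any():
        small = counts[counts < grid.folds].index.tolist()
        raise ValueError(f"stages with fewer cells than folds: {small}")

    splits = []  # (repeat, fold, train_idx, test_idx)
    for rep in range(grid.repeats):
        skf = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=seed + rep)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            splits.append((rep, fold, tr, te))

    genes = [f"g{i}" for i in range(X.shape[1])]  # positional placeholders
    rows = []
    for dropout, l2 in grid.points:
        point_spec = replace(spec, dropout=dropout, l2=l2,
                             epochs=cv_epochs or spec.epochs)
        accs = []
        for rep, fold, tr, te in splits:
            tm = train(X[tr], y.iloc[tr], point_spec, scheme, genes)
            from .classifier import softmax, _forward

            logits, _ = _forward(tm.params, X[te], 1.0, None)
            pred = np.asarray(tm.stages)[softmax(logits).argmax(axis=1)]
            accs.append(float(np.mean(pred == y.iloc[te].to_numpy())))
        rows.append({"dropout": dropout, "l2": l2,
                     "mean_acc": float(np.mean(accs)), "sd_acc": float(np.std(accs))})

    table = pd.DataFrame(rows)
    return CVResult(
        table=table,
        best=select_best(table),
        fold_assignments=[(rep, fold, te.copy()) for rep, fold, _, te in splits],
    )
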