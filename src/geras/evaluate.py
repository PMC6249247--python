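"""Classifier evaluation: accuracy, binomial SE, precision/recall/F1,
cross-tabulation ("balloon") tables, and adjacent-stage rates for
interpolation cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import StageScheme


def _as_arrays(pred, truth):
    pred, truth = np.asarray(pred, dtype=object), np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    return pred, truth


def accuracy(pred, truth) -> float:
    """Proportion of cells whose predicted stage matches the true stage."""
    pred, truth = _as_arrays(pred, truth)
    return float(np.mean(pred == truth))


def binomial_se(acc: float, n: int) -> float:
    """Standard error sqrt(acc * (1 - acc) / n) of a binomial accuracy on n cells."""
    if not 0 <= acc <= 1:
        raise ValueError("accuracy must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(np.sqrt(acc * (1.0 - acc) / n))


def precision_recall_f1(pred, truth, stage) -> tuple:
    """One-vs-rest precision, recall and F1 for one stage.

    Zero-denominator precision or recall is defined as 0 (with a warning)
    so F1 is always a number.
    """
    pred, truth = _as_arrays(pred, truth)
    labels = set(pred) | set(truth)
    if stage not in labels:
        warnings.warn(f"stage {stage!r} never predicted nor true", stacklevel=2)
    tp = int(np.sum((pred == stage) & (truth == stage)))
    fp = int(np.sum((pred == stage) & (truth != stage)))
    fn = int(np.sum((pred != stage) & (truth == stage)))
    if tp + fp == 0:
        warnings.warn(f"no predictions for stage {stage!r}; precision set to 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn(f"no true cells for stage {stage!r}; recall set to 0", stacklevel=2)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


@dataclass
class ClassificationTable:
    """Counts and row-percentages of predicted stages per true group.

    The percentage grid is the numeric content of a balloon plot: each
    row is a cohort, each column a predicted stage, each entry the share
    of the cohort's cells (rounded half-up to one decimal).
    """

    counts: pd.DataFrame
    percents: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        sums = self.percents.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=0.1):
            raise ValueError("row percentages must sum to 100 (±0.1)")


def _round_half_up(x: np.ndarray, decimals: int = 1) -> np.ndarray:
    factor = 10.0 ** decimals
    return np.floor(x * factor + 0.5) / factor


def classification_table(pred, groups) -> ClassificationTable:
    """Cross-tabulate predicted stage by cohort with row percentages."""
    pred, groups = _as_arrays(pred, groups)
    counts = pd.crosstab(pd.Series(groups, name="group"), pd.Series(pred, name="predicted"))
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct = pd.DataFrame(_round_half_up(pct.to_numpy()), index=pct.index, columns=pct.columns)
    return ClassificationTable(counts=counts, percents=pct)


def adjacent_stage_rate(pred, flank_pair: tuple, scheme: StageScheme) -> float:
    """Fraction of predictions falling into either flank of an intermediate cohort.

    Used for interpolation cohorts sampled between two training stages: a
    well-behaved classifier sends nearly all such cells to one of the two
    neighboring (flank) stages.
    """
    a, b = flank_pair
    if not scheme.are_adjacent(a, b):
        raise ValueError(f"stages {a!r} and {b!r} are not adjacent in the scheme")
    pred = np.asarray(pred, dtype=object)
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    return float(np.mean((pred == a) | (pred == b)))


def evaluation_report(pred, truth, stages) -> pd.DataFrame:
    """Per-stage precision/recall/F1 plus overall accuracy and its SE."""
    pred, truth = _as_arrays(pred, truth)
    rows = []
    for s in stages:
        p, r, f = precision_recall_f1(pred, truth, s)
        rows.append({"stage": s, "precision": p, "recall": r, "f1": f})
    df = pd.DataFrame(rows)
    acc = accuracy(pred, truth)
    df.attrs["accuracy"] = acc
    df.attrs["se"] = binomial_se(acc, len(pred))
    df.attrs["n"] = int(len(pred))
    return df


def balloon_plot(table: ClassificationTable, path) -> None:
    """Render the percentage grid as a balloon plot (dot size = percent)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct = table.percents
    fig, ax = plt.subplots(figsize=(1.2 * len(pct.columns) + 2, 1.0 * len(pct.index) + 2))
    for i, grp in enumerate(pct.index):
        for j, stage in enumerate(pct.columns):
            v = pct.loc[grp, stage]
            ax.scatter(j, i, s=20 * v, alpha=0.6, color="tab:blue")
            ax.annotate(f"{v:.1f}", (j, i), ha="center", va="center", fontsize=8)
    ax.set_xticks(range(len(pct.columns)), pct.columns)
    ax.set_yticks(range(len(pct.index)), pct.index)
    ax.set_xlabel("predicted stage")
    ax.set_ylabel("group")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
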