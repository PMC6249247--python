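"""Classification-stratified statistics.

* Two-sided Fisher's exact test on 2x2 stage-by-cohort tables, using the
  conditional hypergeometric distribution: with margins fixed, the p-value
  sums the probabilities of all tables at most as probable as the observed
  one (within a 1e-7 relative tolerance, the convention of R's
  ``fisher.test``).  Log-factorials keep the enumeration stable.
* Welch's unequal-variance t-test and Benjamini-Hochberg FDR control, the
  workhorses of the differential-expression comparison between cells the
  classifier assigns to different stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .expr import ExpressionMatrix

#: relative tolerance when comparing table probabilities to the observed one
_FISHER_RELTOL = 1e-7


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("table entries must be nonnegative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one positive margin")

    @classmethod
    def from_array(cls, arr) -> "ContingencyTable2x2":
        arr = np.asarray(arr)
        if arr.shape != (2, 2):
            raise ValueError("expected a 2x2 array")
        return cls(int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1]))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Accepts a :class:`ContingencyTable2x2` or any 2x2 array-like.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2.from_array(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    lgam = scipy.special.gammaln

    def log_prob(x: int) -> float:
        # hypergeometric pmf of x successes in the first row, margins fixed
        return (
            lgam(r1 + 1) - lgam(x + 1) - lgam(r1 - x + 1)
            + lgam(r2 + 1) - lgam(c1 - x + 1) - lgam(r2 - c1 + x + 1)
            - (lgam(n + 1) - lgam(c1 + 1) - lgam(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    logp_obs = log_prob(a)
    cutoff = logp_obs + np.log1p(_FISHER_RELTOL)
    total = sum(np.exp(log_prob(x)) for x in range(lo, hi + 1) if log_prob(x) <= cutoff)
    return float(min(total, 1.0))


def welch_t(x, y) -> tuple:
    """Welch's two-sided unequal-variance t-test; returns (t, p).

    Degenerate inputs (zero variance in both groups) yield p = 1 when the
    means are equal and p = 0 (with a warning) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn("zero variance in both groups with unequal means", stacklevel=2)
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if ((pvals < 0) | (pvals > 1)).any() or not np.all(np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return qvals


def differential_expression(
    m: ExpressionMatrix, group_a, group_b, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-gene Welch t-test between two disjoint cell groups with BH control.

    ``m`` must hold log2-transformed values; the log2 fold-change is the
    difference of group means (A minus B).  Genes with zero variance in
    both groups and equal means are untestable and reported with
    ``tested=False``.  Returns a volcano-ready table: mean_a, mean_b,
    log2_fc, t, p, q and a significance flag at ``q < fdr``.
    """
    if m.unit != "log2":
        raise ValueError(f"differential expression expects log2 values, got {m.unit!r}")
    group_a = pd.Index(group_a, dtype=object)
    group_b = pd.Index(group_b, dtype=object)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    overlap = group_a.intersection(group_b)
    if len(overlap):
        raise ValueError(f"groups overlap: {overlap[:5].tolist()}")

    A = m.subset_cells(group_a).values
    B = m.subset_cells(group_b).values
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    var_a, var_b = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    untestable = (var_a == 0) & (var_b == 0) & (mean_a == mean_b)

    t = np.full(m.n_genes, np.nan)
    p = np.full(m.n_genes, np.nan)
    testable = ~untestable
    if testable.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            res = scipy.stats.ttest_ind(A[testable], B[testable], axis=1, equal_var=False)
        t[testable], p[testable] = res.statistic, res.pvalue
        # constant-but-different genes: infinite separation
        degen = testable & (var_a == 0) & (var_b == 0)
        t[degen] = np.sign(mean_a[degen] - mean_b[degen]) * np.inf
        p[degen] = 0.0

    q = np.full(m.n_genes, np.nan)
    q[testable] = bh_fdr(p[testable])
    out = pd.DataFrame({
        "gene_id": m.gene_ids,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "log2_fc": mean_a - mean_b,
        "t": t,
        "p": p,
        "q": q,
        "tested": testable,
    })
    out["significant"] = out["q"] < fdr
    return out
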