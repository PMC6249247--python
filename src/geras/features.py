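"""Feature selection: rank genes by median absolute deviation (MAD).

Genes are sorted in descending order of expression variability measured by
the MAD across cells, and the top-k (default 1000) become the classifier's
input layer, in rank order.  The MAD is unscaled by default (no 1.4826
normal-consistency constant): the ranking, and hence the selected gene set,
is invariant to any positive rescaling of the statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expr import ExpressionMatrix

logger = logging.getLogger(__name__)

#: scale factor making the MAD a consistent estimator of the normal sigma
NORMAL_CONSISTENCY = 1.4826


def mad(values, scaled: bool = False) -> float:
    """Median absolute deviation: median(|x_i - median(x)|).

    With ``scaled=True`` the result is multiplied by 1.4826 for consistency
    with the normal standard deviation.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    out = float(np.median(np.abs(values - np.median(values))))
    return out * NORMAL_CONSISTENCY if scaled else out


@dataclass
class GeneRanking:
    """Genes with their MAD values, descending; ties broken by gene id."""

    table: pd.DataFrame  # columns: gene_id, mad

    def __post_init__(self) -> None:
        diffs = np.diff(self.table["mad"].to_numpy())
        if (diffs > 0).any():
            raise ValueError("ranking must be non-increasing in mad")

    @property
    def gene_ids(self) -> list:
        return self.table["gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def rank_genes(
    m: ExpressionMatrix, scaled: bool = False, allow_any_unit: bool = False
) -> GeneRanking:
    """Rank all genes by MAD across cells, descending.

    Variability is normally computed on the normalized linear-scale matrix
    (TPM or RPM); pass ``allow_any_unit=True`` to rank counts or log2 values
    instead.
    """
    if not allow_any_unit and m.unit not in ("TPM", "RPM"):
        raise ValueError(
            f"rank_genes expects a TPM/RPM matrix (got {m.unit!r}); "
            "pass allow_any_unit=True to override"
        )
    if m.n_cells < 1:
        raise ValueError("ranking requires at least one cell")
    med = np.median(m.values, axis=1, keepdims=True)
    mads = np.median(np.abs(m.values - med), axis=1)
    if scaled:
        mads = mads * NORMAL_CONSISTENCY
    df = pd.DataFrame({"gene_id": m.gene_ids, "mad": mads})
    # descending mad; lexicographic gene_id within ties for determinism
    df = df.sort_values(["mad", "gene_id"], ascending=[False, True], kind="mergesort")
    return GeneRanking(df.reset_index(drop=True))


def select_top_k(ranking: GeneRanking, k: int = 1000) -> list:
    """First min(k, n) gene ids in rank order; order fixes input-layer positions."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking):
        logger.warning("k=%d exceeds %d available genes; returning all", k, len(ranking))
    return ranking.gene_ids[:k]
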