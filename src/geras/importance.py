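"""Per-gene importance from the trained network's connection weights.

The default scorer generalizes Garson's connection-weight algorithm to two
hidden layers: the absolute weight matrices are chained, C = |W1| |W2| |W3|,
giving each input gene's total connection strength to each output stage;
a gene's importance is its row sum of C normalized so that importances sum
to one.  Biases carry no per-gene information and are ignored.  A
model-agnostic permutation importance is provided as a cross-check on rank
stability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import TrainedModel
from .expr import ExpressionMatrix


def gene_importance(tm: TrainedModel) -> pd.DataFrame:
    """Connection-weight importance per input gene, descending, summing to 1.

    Returns a DataFrame with columns ``gene_id``, ``importance``, ``rank``.
    """
    W1, W2, W3 = (np.abs(tm.params[k]) for k in ("W1", "W2", "W3"))
    if not all(np.all(np.isfinite(w)) for w in (W1, W2, W3)):
        raise ValueError("model weights contain non-finite values")
    contrib = W1 @ W2 @ W3  # genes x stages
    per_gene = contrib.sum(axis=1)
    total = per_gene.sum()
    if total == 0:
        imp = np.full(len(per_gene), 1.0 / len(per_gene))
    else:
        imp = per_gene / total
    df = pd.DataFrame({"gene_id": tm.genes, "importance": imp})
    df = df.sort_values(["importance", "gene_id"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def permutation_importance(
    tm: TrainedModel, m: ExpressionMatrix, truth, n_repeats: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Accuracy drop when each input gene's values are shuffled across cells.

    Slower but model-agnostic; used to sanity-check the connection-weight
    ranking.  Returns gene_id, importance (mean accuracy drop), rank.
    """
    rng = np.random.default_rng(seed)
    truth = np.asarray(truth, dtype=object)
    X = tm._design_matrix(m)
    from .classifier import _forward, softmax

    def acc(Xm):
        logits, _ = _forward(tm.params, Xm, 1.0, None)
        pred = np.asarray(tm.stages)[softmax(logits).argmax(axis=1)]
        return float(np.mean(pred == truth))

    base = acc(X)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        vals = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            vals.append(base - acc(Xp))
        drops[j] = np.mean(vals)
    df = pd.DataFrame({"gene_id": tm.genes, "importance": drops})
    df = df.sort_values(["importance", "gene_id"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
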