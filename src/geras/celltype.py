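"""Marker-based pancreatic cell typing and cell-type-stratified accuracy.

A cell is assigned the type of its most highly expressed marker gene,
provided that marker exceeds a fixed RPM threshold (default 50); cells with
no marker above threshold are 'Others'.  The default panel covers the major
pancreatic types: INS (beta), GCG (alpha), SST (delta), PRSS1 (acinar) and
KRT19 (ductal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import accuracy, binomial_se
from .expr import ExpressionMatrix

OTHERS = "Others"


@dataclass
class MarkerPanel:
    """Ordered (cell_type, marker gene) pairs with an RPM threshold."""

    markers: list  # list of (cell_type, gene_id), order = tie precedence
    threshold: float = 50.0

    def __post_init__(self) -> None:
        genes = [g for _, g in self.markers]
        if len(set(genes)) != len(genes):
            raise ValueError("marker genes must be unique")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def cell_types(self) -> list:
        return [t for t, _ in self.markers]

    @property
    def genes(self) -> list:
        return [g for _, g in self.markers]

    @classmethod
    def human_pancreas(cls) -> "MarkerPanel":
        return cls([
            ("beta", "INS"),
            ("alpha", "GCG"),
            ("delta", "SST"),
            ("acinar", "PRSS1"),
            ("ductal", "KRT19"),
        ])


def assign_cell_type(rpm_values, panel: MarkerPanel) -> str:
    """Type of the highest-expressed marker if it exceeds the threshold, else 'Others'.

    ``rpm_values`` maps marker gene id -> RPM for one cell; missing markers
    count as 0 (with a warning).  Exact ties among maximal markers resolve
    by panel order, with a warning.
    """
    vals = []
    for _, gene in panel.markers:
        if gene in rpm_values:
            vals.append(float(rpm_values[gene]))
        else:
            warnings.warn(f"marker {gene!r} missing; treated as 0 RPM", stacklevel=2)
            vals.append(0.0)
    vals = np.asarray(vals)
    top = vals.max()
    if top <= panel.threshold:
        return OTHERS
    winners = np.flatnonzero(vals == top)
    if len(winners) > 1:
        tied = [panel.cell_types[i] for i in winners]
        warnings.warn(f"tied maximal markers {tied}; using panel order", stacklevel=2)
    return panel.cell_types[int(winners[0])]


def assign_cell_types(m: ExpressionMatrix, panel: MarkerPanel) -> pd.Series:
    """Per-cell type assignment for an RPM matrix."""
    if m.unit != "RPM":
        raise ValueError(f"cell typing requires RPM values, got unit {m.unit!r}")
    # extract marker rows directly: a marker-only submatrix would no longer
    # satisfy the RPM column-sum invariant
    rows = np.zeros((len(panel.genes), m.n_cells))
    for i, gene in enumerate(panel.genes):
        if gene in m.gene_ids:
            rows[i] = m.values[m.gene_ids.get_loc(gene)]
        else:
            warnings.warn(f"marker {gene!r} absent from matrix; treated as 0 RPM",
                          stacklevel=2)
    labels = [
        assign_cell_type(dict(zip(panel.genes, rows[:, c])), panel)
        for c in range(m.n_cells)
    ]
    return pd.Series(labels, index=m.cell_ids, name="cell_type")


def per_celltype_accuracy(pred, truth, cell_types) -> pd.DataFrame:
    """Stage-classification accuracy, binomial SE and n within each cell type."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    cell_types = np.asarray(cell_types, dtype=object)
    if not (len(pred) == len(truth) == len(cell_types)):
        raise ValueError("pred, truth and cell_types must be aligned")
    rows = []
    for ct in pd.unique(cell_types):
        mask = cell_types == ct
        n = int(mask.sum())
        acc = accuracy(pred[mask], truth[mask])
        rows.append({"cell_type": ct, "accuracy": acc, "se": binomial_se(acc, n), "n": n})
    return pd.DataFrame(rows)
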