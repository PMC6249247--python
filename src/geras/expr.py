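"""Expression matrices: I/O, normalization, log transform, QC filtering.

The central container is :class:`ExpressionMatrix`, a genes x cells matrix
with a unit tag (``counts``, ``TPM``, ``RPM`` or ``log2``) and optional
per-cell metadata (age, stage, batch, group).  Counts are normalized either
to transcripts per million (TPM; length-corrected) or reads per million
(RPM; library-size only), after which each cell's column sums to one
million.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

VALID_UNITS = ("counts", "TPM", "RPM", "log2")

#: relative tolerance on per-cell sums for TPM/RPM matrices
MILLION_RTOL = 1e-6


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values plus per-cell metadata.

    Parameters
    ----------
    values
        2-D float array, genes in rows, cells in columns, nonnegative.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    unit
        One of ``counts``, ``TPM``, ``RPM``, ``log2``.
    cell_meta
        Optional table indexed by cell id (columns such as ``age``,
        ``age_unit``, ``stage``, ``batch``, ``group``).
    """

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    unit: str = "counts"
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        self.cell_ids = pd.Index(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        for name, idx in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if idx.has_duplicates:
                dups = idx[idx.duplicated()].unique().tolist()
                raise ValueError(f"duplicate {name} ids: {dups}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.unit in ("TPM", "RPM") and self.n_cells:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1e6, rtol=MILLION_RTOL):
                bad = self.cell_ids[~np.isclose(sums, 1e6, rtol=MILLION_RTOL)]
                raise ValueError(
                    f"{self.unit} columns must sum to 1e6; offending cells: "
                    f"{bad[:5].tolist()}"
                )
        if not self.cell_meta.empty:
            missing = self.cell_ids.difference(self.cell_meta.index)
            if len(missing):
                raise ValueError(f"cells missing from metadata: {missing[:5].tolist()}")
            name = self.cell_meta.index.name
            self.cell_meta = self.cell_meta.loc[self.cell_ids]
            self.cell_meta.index.name = name

    # -- basic views ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order preserved as given).

        Genes absent from the matrix are filled with zeros; a count of the
        imputed genes is logged (needed when applying a trained model to a
        matrix filtered upstream).
        """
        genes = pd.Index(genes, dtype=object)
        present = genes.isin(self.gene_ids)
        n_missing = int((~present).sum())
        if n_missing:
            logger.warning("%d of %d requested genes absent; imputed as 0", n_missing, len(genes))
        out = np.zeros((len(genes), self.n_cells))
        pos = self.gene_ids.get_indexer(genes[present])
        out[np.flatnonzero(present)] = self.values[pos]
        return ExpressionMatrix(out, genes, self.cell_ids, self.unit, self.cell_meta.copy())

    def subset_cells(self, cells) -> "ExpressionMatrix":
        cells = pd.Index(cells, dtype=object)
        missing = cells.difference(self.cell_ids)
        if len(missing):
            raise KeyError(f"unknown cells: {missing[:5].tolist()}")
        pos = self.cell_ids.get_indexer(cells)
        meta = self.cell_meta.loc[cells] if not self.cell_meta.empty else pd.DataFrame()
        return ExpressionMatrix(self.values[:, pos], self.gene_ids, cells, self.unit, meta)


@dataclass
class GeneLengthTable:
    """Gene lengths in kilobases, used for TPM normalization."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        self.lengths = pd.Series(self.lengths, dtype=float)
        self.lengths.index = pd.Index(self.lengths.index, dtype=object)
        if self.lengths.index.has_duplicates:
            raise ValueError("duplicate gene ids in length table")
        if not (self.lengths > 0).all():
            bad = self.lengths.index[~(self.lengths > 0)].tolist()
            raise ValueError(f"gene lengths must be > 0 kb; offending: {bad[:5]}")

    def __getitem__(self, gene_id: str) -> float:
        return float(self.lengths[gene_id])

    @classmethod
    def from_tsv(cls, path) -> "GeneLengthTable":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        return cls(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"gene_id": self.lengths.index, "length_kb": self.lengths.values})
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(
    path,
    format: str | None = None,
    transpose: bool = False,
    meta_path=None,
) -> ExpressionMatrix:
    """Read a count matrix from TSV/CSV/MTX into an ExpressionMatrix.

    TSV/CSV: first column gene ids, header row cell ids.  MTX: MatrixMarket
    coordinate file with ``<stem>.genes.txt`` / ``<stem>.cells.txt`` sidecar
    id files (one id per line).  ``meta_path`` points to an optional TSV
    keyed by ``cell_id`` with columns such as age, age_unit, batch, group.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric entries in {path}: {exc}") from exc
        gene_ids, cell_ids = df.index.astype(str), df.columns.astype(str)
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        stem = path.with_suffix("")
        gene_ids = pd.Index(Path(f"{stem}.genes.txt").read_text().split(), dtype=object)
        cell_ids = pd.Index(Path(f"{stem}.cells.txt").read_text().split(), dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}")
    if transpose:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    meta = pd.DataFrame()
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str}).set_index("cell_id")
    return ExpressionMatrix(values, gene_ids, cell_ids, unit="counts", cell_meta=meta)


def write_expression(m: ExpressionMatrix, path, format: str = "tsv") -> None:
    sep = "\t" if format == "tsv" else ","
    m.to_frame().rename_axis("gene_id").to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _check_counts(m: ExpressionMatrix, op: str) -> None:
    if m.unit != "counts":
        raise ValueError(f"{op} expects unit='counts', got {m.unit!r}")


def tpm_normalize(m: ExpressionMatrix, lengths: GeneLengthTable) -> ExpressionMatrix:
    """Transcripts per million: counts / gene length (kb), scaled per cell to 1e6.

    For gene g and cell c, transcripts_gc = counts_gc / length_kb_g and
    TPM_gc = transcripts_gc / sum_g transcripts_c * 1e6.
    """
    _check_counts(m, "tpm_normalize")
    missing = m.gene_ids.difference(lengths.lengths.index)
    if len(missing):
        raise KeyError(f"genes missing from length table: {missing[:5].tolist()}")
    kb = lengths.lengths.reindex(m.gene_ids).to_numpy()
    transcripts = m.values / kb[:, None]
    totals = transcripts.sum(axis=0)
    if (totals <= 0).any():
        bad = m.cell_ids[totals <= 0].tolist()
        raise ValueError(f"cells with zero total counts cannot be TPM-normalized: {bad[:5]}")
    tpm = transcripts / totals * 1e6
    return ExpressionMatrix(tpm, m.gene_ids, m.cell_ids, "TPM", m.cell_meta.copy())


def rpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per million: counts scaled per cell to a total of 1e6 (no length term)."""
    _check_counts(m, "rpm_normalize")
    totals = m.values.sum(axis=0)
    if (totals <= 0).any():
        bad = m.cell_ids[totals <= 0].tolist()
        raise ValueError(f"cells with zero total counts cannot be RPM-normalized: {bad[:5]}")
    rpm = m.values / totals * 1e6
    return ExpressionMatrix(rpm, m.gene_ids, m.cell_ids, "RPM", m.cell_meta.copy())


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(x + pseudocount) of a TPM or RPM matrix.

    The pseudocount (default 1) keeps zeros finite and maps 0 -> 0.
    """
    if m.unit not in ("TPM", "RPM"):
        raise ValueError(f"log_transform expects TPM or RPM input, got {m.unit!r}")
    if pseudocount < 1:
        # log2(x + c) < 0 for x < 1 - c, violating the nonnegativity invariant
        raise ValueError("pseudocount must be >= 1")
    vals = np.log2(m.values + pseudocount)
    return ExpressionMatrix(vals, m.gene_ids, m.cell_ids, "log2", m.cell_meta.copy())


def qc_filter(
    m: ExpressionMatrix, min_genes_detected: int = 0, min_total_counts: float = 0
) -> ExpressionMatrix:
    """Drop cells detecting fewer genes or fewer total counts than the thresholds.

    Removed cell ids and the reason are logged.  Removing every cell yields
    an empty matrix with a warning rather than an error.
    """
    _check_counts(m, "qc_filter")
    if min_genes_detected < 0 or min_total_counts < 0:
        raise ValueError("QC thresholds must be nonnegative")
    detected = (m.values > 0).sum(axis=0)
    totals = m.values.sum(axis=0)
    keep = (detected >= min_genes_detected) & (totals >= min_total_counts)
    for cid, d, t, k in zip(m.cell_ids, detected, totals, keep):
        if not k:
            reason = []
            if d < min_genes_detected:
                reason.append(f"genes_detected={d}<{min_genes_detected}")
            if t < min_total_counts:
                reason.append(f"total_counts={t}<{min_total_counts}")
            logger.info("qc_filter removed cell %s (%s)", cid, "; ".join(reason))
    if not keep.any():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    meta = m.cell_meta.loc[m.cell_ids[keep]] if not m.cell_meta.empty else pd.DataFrame()
    return ExpressionMatrix(m.values[:, keep], m.gene_ids, m.cell_ids[keep], m.unit, meta)
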