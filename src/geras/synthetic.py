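"""Synthetic stage-labelled single-cell count matrices.

The generator emulates the statistical structure a chronological-stage
classifier relies on: a minority of informative genes whose mean expression
drifts monotonically across stages, overdispersed negative-binomial counts,
mean-dependent technical dropout (zero inflation) and variable library
sizes.  Intermediate cohorts — cells sampled between two adjacent stages —
are generated by interpolating the log2 mean trajectories, mimicking
animals sampled between the training stages.

All draws are deterministic given the spec's seed, and the ground truth
(informative gene set and trajectories) accompanies every dataset so that
feature selection and importance ranking can be validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expr import ExpressionMatrix, GeneLengthTable


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic single-cell dataset.

    Defaults give 3 stages x 200 cells x 2000 genes of which 200 are
    informative with per-stage log2 steps of 0.5-2.0 (random sign),
    negative-binomial dispersion 0.4, logistic mean-dependent dropout and
    2x library-size variation.
    """

    n_stages: int = 3
    cells_per_stage: int = 200
    n_genes: int = 2000
    n_informative: int = 200
    log2_step_range: tuple = (0.5, 2.0)
    baseline_log_mean: float = 1.5   # natural-log mean of baseline counts
    baseline_log_sd: float = 1.0    # natural-log sd of baseline counts
    dispersion: float = 0.4          # NB: var = mu + dispersion * mu^2
    dropout_midpoint: float = 1.0    # log2(mu+1) at which dropout prob = 0.5
    dropout_steepness: float = 1.5
    library_factor_range: tuple = (0.5, 2.0)
    gene_length_range_kb: tuple = (0.5, 5.0)
    stage_labels: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.n_stages < 2 or self.cells_per_stage < 1 or self.n_genes < 1:
            raise ValueError("invalid dataset dimensions")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.log2_step_range
        if not 0 < lo <= hi:
            raise ValueError("invalid log2 step range")
        if not self.stage_labels:
            self.stage_labels = tuple(f"stage{i}" for i in range(self.n_stages))
        if len(self.stage_labels) != self.n_stages:
            raise ValueError("stage_labels length must equal n_stages")

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, indent=2)


@dataclass
class SyntheticTruth:
    """Ground truth written beside every generated dataset."""

    informative_genes: list
    log2_trajectories: np.ndarray  # n_genes x n_stages log2-mean trajectories
    gene_ids: list
    spec: SyntheticSpec

    def to_json(self) -> str:
        return json.dumps({
            "informative_genes": self.informative_genes,
            "gene_ids": self.gene_ids,
            "log2_trajectories": self.log2_trajectories.tolist(),
            "spec": asdict(self.spec),
        }, default=list)


def _trajectories(spec: SyntheticSpec, rng: np.random.Generator):
    """Per-gene log2 mean trajectory over stages; monotone for informative genes."""
    gene_ids = [f"gene{i:04d}" for i in range(spec.n_genes)]
    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    log2_base = baseline / np.log(2)
    traj = np.tile(log2_base[:, None], (1, spec.n_stages))
    informative = rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    informative.sort()
    steps = rng.uniform(*spec.log2_step_range, size=spec.n_informative)
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
    for g, s in zip(informative, signs * steps):
        traj[g] = log2_base[g] + s * np.arange(spec.n_stages)
    return gene_ids, traj, [gene_ids[i] for i in informative]


def _sample_counts(
    log2_means: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """NB + dropout counts for a genes x cells matrix of log2 mean expression."""
    n_genes, n_cells = log2_means.shape
    lib = rng.uniform(*spec.library_factor_range, size=n_cells)
    mu = np.exp2(log2_means) * lib  # library factor scales every gene of a cell
    # negative binomial with var = mu + dispersion mu^2  =>  shape r = 1/dispersion
    r = 1.0 / spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    # technical dropout: logistic, decreasing in the underlying mean
    p_drop = 1.0 / (1.0 + np.exp(
        spec.dropout_steepness * (np.log2(mu + 1.0) - spec.dropout_midpoint)
    ))
    counts[rng.random(counts.shape) < p_drop] = 0.0
    return counts


def generate_dataset(spec: SyntheticSpec):
    """Generate (counts matrix, stage labels, gene lengths, truth).

    Cells are balanced across stages; metadata carries the stage label and a
    numeric pseudo-age equal to the stage index.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids, traj, informative = _trajectories(spec, rng)

    n_cells = spec.n_stages * spec.cells_per_stage
    stage_idx = np.repeat(np.arange(spec.n_stages), spec.cells_per_stage)
    log2_means = traj[:, stage_idx]  # genes x cells
    counts = _sample_counts(log2_means, spec, rng)

    cell_ids = [f"cell{j:04d}" for j in range(n_cells)]
    labels = pd.Series([spec.stage_labels[i] for i in stage_idx], index=cell_ids, name="stage")
    meta = pd.DataFrame({
        "age": stage_idx.astype(float),
        "age_unit": "stage_index",
        "stage": labels.values,
        "batch": "synthetic",
        "group": "synthetic",
    }, index=pd.Index(cell_ids, name="cell_id"))

    m = ExpressionMatrix(counts, gene_ids, cell_ids, unit="counts", cell_meta=meta)
    lengths = GeneLengthTable(pd.Series(
        rng.uniform(*spec.gene_length_range_kb, size=spec.n_genes), index=gene_ids
    ))
    truth = SyntheticTruth(informative, traj, gene_ids, spec)
    return m, labels, lengths, truth


def generate_intermediate(
    spec: SyntheticSpec, flank: tuple, mix: float, n_cells: int, seed: int | None = None
) -> ExpressionMatrix:
    """Cells whose log2 means interpolate between two adjacent stages.

    ``flank`` gives the indices (i, i+1) of the neighboring stages and
    ``mix`` in [0, 1] the position between them (0 = stage i exactly).
    The gene trajectories are those of the base dataset (same spec seed), so
    the cohort can be classified by a model trained on that dataset.
    """
    i, j = flank
    if j != i + 1 or not 0 <= i < spec.n_stages - 1:
        raise ValueError(f"flank stages {flank} must be adjacent indices")
    if not 0 <= mix <= 1:
        raise ValueError("mix must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    gene_ids, traj, _ = _trajectories(spec, rng)  # replays the base trajectories
    if seed is not None:
        rng = np.random.default_rng(seed)
    log2_means = (1 - mix) * traj[:, [i]] + mix * traj[:, [j]]
    counts = _sample_counts(np.tile(log2_means, (1, n_cells)), spec, rng)
    cell_ids = [f"mix{i}{j}_{k:04d}" for k in range(n_cells)]
    return ExpressionMatrix(counts, gene_ids, cell_ids, unit="counts")


def generate_xor_dataset(
    n_pairs: int = 10,
    n_noise_genes: int = 500,
    cells_per_stage: int = 200,
    log2_high: float = 4.0,
    noise_sd: float = 0.6,
    seed: int = 0,
):
    """Two-stage dataset whose signal lives in two-gene interactions.

    Each informative gene pair encodes the stage as the exclusive-or of the
    two genes' high/low states: stage A cells express exactly one gene of a
    pair highly, stage B cells both or neither.  Every single gene has the
    same marginal distribution in both stages, so no linear (multinomial
    logistic) decision rule can separate them, while a network with hidden
    units can.  Values are returned as a log2-unit matrix plus labels.
    """
    rng = np.random.default_rng(seed)
    n_genes = 2 * n_pairs + n_noise_genes
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    stages = ("stageA", "stageB")
    n_cells = 2 * cells_per_stage
    X = rng.normal(0.0, noise_sd, size=(n_genes, n_cells))
    labels = np.repeat(stages, cells_per_stage)
    for c in range(n_cells):
        for p in range(n_pairs):
            if labels[c] == "stageA":
                hot = rng.integers(2)  # exactly one of the pair high
                X[2 * p + hot, c] += log2_high
            else:
                if rng.integers(2):    # both or neither high
                    X[2 * p, c] += log2_high
                    X[2 * p + 1, c] += log2_high
    X = np.clip(X, 0.0, None)
    cell_ids = [f"cell{j:04d}" for j in range(n_cells)]
    m = ExpressionMatrix(X, gene_ids, cell_ids, unit="log2")
    return m, pd.Series(labels, index=cell_ids, name="stage"), stages
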