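# Methods

## The problem

Single-cell RNA sequencing captures a cell's transcriptional state, which
drifts with the age of the organism the cell came from.  `geras` treats
chronological age as a supervised classification problem: given a gene x
cell read-count matrix whose cells carry known age labels, collapse the ages
into a small ordered set of chronological stages (e.g. Juvenile <
Adolescent < Adult for zebrafish beta-cells, or Juvenile < Young < Middle
for human pancreatic donors) and train a classifier that assigns any new
cell a stage, together with a softmax probability over all stages.  The
probabilities make the discrete classifier usable on interpolation tasks:
cells sampled from ages between two training stages should split their
probability mass between the flanking stages and give almost none to the
distant stage.

## Normalization

Counts are normalized per cell before anything else.

* **TPM** (transcripts per million): `transcripts_gc = counts_gc /
  length_kb_g`, then `TPM_gc = transcripts_gc / Σ_g transcripts_c * 1e6`.
  Requires a gene-length table in kilobases covering every gene.
* **RPM** (reads per million): `RPM_gc = counts_gc / Σ_g counts_c * 1e6`,
  no length correction (appropriate when all genes were measured with a
  comparable protocol, as in the human pancreas calibration).

Either way each cell's column sums to exactly one million; the
`ExpressionMatrix` container enforces this invariant (relative tolerance
1e-6) whenever a matrix is tagged TPM or RPM.  A cell with zero total
counts is an error at normalization time — `qc_filter` (minimum genes
detected, minimum total counts) is the sanctioned removal path, and it
logs every removed cell with its reason.

Network inputs are `log2(x + 1)` of the normalized values.  The published
procedure says only "log2-transformed"; the +1 pseudocount is the standard
way to keep the ubiquitous scRNA-seq zeros finite and maps 0 to 0.  It is
configurable (`log_transform(pseudocount=...)`, constrained to >= 1 so the
nonnegativity invariant holds).

## Feature selection

Genes are ranked by the **median absolute deviation** (MAD) of their
normalized expression across all cells, descending, and the top 1000 become
the network's input layer, in rank order (the order is part of the model
contract — it fixes input positions).  Choices made here:

* MAD is unscaled (no 1.4826 normal-consistency factor).  Ranking is
  invariant to positive rescaling, so the selected set is identical either
  way; a `scaled=True` flag exists for parity with other conventions.
* MAD is computed on the linear TPM/RPM matrix by default, since
  variability is assessed on the normalized dataset before model building;
  `allow_any_unit=True` permits ranking log2 or raw counts instead.
* Ties break lexicographically by gene id, so rankings are bit-reproducible
  across platforms.

## The classifier

A four-layer fully connected network: input (1000 genes) → hidden ReLU →
hidden ReLU → softmax over stages.  The hidden widths are not dictated by
the published topology; the defaults are 64 and 32 — small relative to the
~500-cell training sets to limit overfitting — and configurable.

Two regularizers, tuned rather than fixed:

* **Dropout** on both hidden layers, parameterized as the **keep
  probability** (0.8 keeps 80% of units each step; 1.0 disables it).  The
  published grid 0.4–0.9 reads naturally as keep rates — dropping 90% of
  units would be pathological.  Implemented as inverted dropout: masks are
  Bernoulli(keep)/keep at training time, nothing at inference.
* **L2**: `l2 * Σ W²` over all three weight matrices (biases unpenalized),
  added to the mean cross-entropy.  This penalizes a strong focus on few
  inputs.  Empirically the published grid magnitudes (0.2–1.6) still train
  to >95% held-out accuracy on the synthetic data under this definition.

Training is full-batch Adam (lr 1e-3, 400 epochs by default), He-normal
initialization, everything driven by a single numpy `Generator` seeded from
the model spec — identical data and seed reproduce identical weights.  The
optimizer, epoch count and initialization are this package's choices; the
original procedure fixes none of them, so accuracy parity with the original
real-data runs is not a contract of this implementation.  A non-finite loss
aborts with a diagnostic rather than silently producing NaN weights.

At prediction time the recorded transform spec (normalization unit + log2
flag) is re-applied; genes in the model's list but absent from the incoming
matrix are imputed as 0 after transform with a logged count, which is what
makes cross-batch classification work on matrices filtered upstream.
Stage calls are the argmax of the softmax; exact ties resolve toward the
earlier stage with a warning.

### Hyperparameter tuning

Stratified 5-fold cross-validation repeated 3 times (folds re-randomized
per repeat, all seeded) over the (dropout, L2) grid; the same fold
partitions are reused for every grid point so points are compared on equal
footing.  The published grids are 0.4–0.9 step 0.1 (dropout) crossed with
0.4–1.6 step 0.2 (zebrafish, 42 points) or 0.2–1.2 step 0.2 (human, 36
points).  Mean accuracy is taken over the folds x repeats evaluations
(averaging evaluations rather than pooling predictions; the difference is
negligible at these sizes).  The argmax wins; ties prefer smaller L2, then
larger keep probability — the less constrained model among equals.  A
`cv_epochs` option trains with a reduced epoch budget during CV while the
final fit keeps the full budget.

### Baseline

`logistic_baseline_accuracy` fits a multinomial logistic regression
(scikit-learn) on exactly the same design matrix, as the linear reference
point.  On stage signatures carried by two-gene interactions (the XOR-style
synthetic dataset) the linear model is at chance by construction while the
network is not.

## Evaluation

Accuracy is the proportion of cells whose call matches the true stage; its
error bar treats each classification as a binomial draw, `SE =
sqrt(acc (1-acc) / n)`.  Per-stage precision, recall and F1 are one-vs-rest;
zero-denominator cases are defined as 0 with a warning so F1 is always a
number.  `classification_table` cross-tabulates calls by cohort with row
percentages (rounded half-up to one decimal; raw counts always kept
alongside) — the numeric content of a balloon plot, which
`balloon_plot` renders if matplotlib is available.  For interpolation
cohorts, `adjacent_stage_rate` is the fraction of calls landing in either
flanking stage.

## Gene importance

The importance of each input gene is computed from the strength of the
trained network's connections: with `C = |W1| |W2| |W3|` (genes x stages),
a gene's importance is its row sum of C normalized to a total of 1.  This
is Garson's connection-weight algorithm generalized to two hidden layers;
biases are excluded since they carry no per-gene information.  The scores
are nonnegative, sum to one, are invariant to positive rescaling of all
weights, and permute with gene relabeling.  A slower permutation importance
(mean accuracy drop when one gene's values are shuffled across cells) is
available as a rank-stability cross-check.  Per-gene values from any
particular published model are not reproducible targets — they depend on
that model's trained weights.

## Marker-based cell typing

For the pancreas, a cell is typed by its most highly expressed marker among
INS (beta), GCG (alpha), SST (delta), PRSS1 (acinar), KRT19 (ductal),
provided that marker *exceeds* 50 RPM (strict inequality); otherwise it is
'Others'.  Missing markers count as 0 with a warning; exact ties (measure
zero in practice) resolve by panel order with a warning.  The threshold and
panel are configurable.  `per_celltype_accuracy` then stratifies the stage
classifier's accuracy (with binomial SE) by assigned type.

## Classification-stratified statistics

* `fisher_exact_2x2`: two-sided Fisher's exact test for 2x2 cohort-by-stage
  tables.  With margins fixed, the p-value sums the hypergeometric
  probabilities of all tables whose probability is at most the observed
  one times (1 + 1e-7) — the relative-tolerance convention of R's
  `fisher.test`, so printed significance bounds are comparable.  Computed
  with log-factorials (gammaln) for stability; validated in tests against
  an exact rational enumeration and against scipy.
* `differential_expression`: per-gene Welch unequal-variance t-tests on
  log2 values between two disjoint groups of cells (typically cells the
  classifier assigned to different stages), Benjamini–Hochberg FDR across
  tested genes, significance flagged at q < 0.05.  The log2 fold-change is
  the difference of group means.  Genes with zero variance in both groups
  and equal means are untestable and reported with `tested=False`.  The
  reproducibility-optimized test statistic some published analyses use is a
  separately published method; this package deliberately ships the plain
  Welch + BH combination and leaves the interface open to other statistics,
  so specific published DE gene counts are not reproduction targets.

## Synthetic data

`generate_dataset` produces the stage-labelled data every other module is
tested on, with the structure the classifier assumes:

| parameter | default | meaning |
|---|---|---|
| n_stages / cells_per_stage | 3 / 200 | balanced stage design |
| n_genes / n_informative | 2000 / 200 | 10% of genes carry age signal |
| log2_step_range | (0.5, 2.0) | per-stage drift of an informative gene, random sign, monotone across stages |
| baseline_log_mean / sd | 1.5 / 1.0 | log-normal baseline mean counts (median ≈ 4.5) |
| dispersion | 0.4 | negative binomial, var = μ + 0.4 μ² |
| dropout_midpoint / steepness | 1.0 / 1.5 | logistic P(zero) decreasing in log2(μ+1) |
| library_factor_range | (0.5, 2.0) | uniform per-cell depth factor |
| gene_length_range_kb | (0.5, 5.0) | uniform, for TPM |

Counts are NB draws around stage-trajectory means scaled by the cell's
library factor, then zeroed by mean-dependent dropout.
`generate_intermediate` interpolates the *log2* trajectories between two
adjacent stages (geometric interpolation of means, matching the log2-scale
step construction) and applies the same noise model — the analogue of
sampling animals between training stages.  `generate_xor_dataset` encodes a
two-stage label purely in two-gene interactions (one-of-a-pair high vs
both-or-neither high), leaving every single-gene marginal identical across
stages.

What the generator does *not* emulate: batch effects, cell-type mixtures,
gene–gene correlation beyond the stage signal, amplification noise specific
to any chemistry, or the empirical distributions of any deposited dataset.
Passing tests therefore demonstrate that the pipeline recovers structure of
this assumed form at realistic noise levels — not that any particular
real-data accuracy would be matched.

## Problem sizes and numerical choices

The test and acceptance runs use the generator defaults (2000 genes, 600
cells), a reduced 2x2 hyperparameter grid with 100 CV epochs and a 300-epoch
final fit — sizes at which a full tune-train-evaluate cycle completes in
well under a minute on one CPU while leaving the acceptance margins (>= 90%
held-out accuracy, >= 95% adjacent-stage rate) comfortably cleared.
Tolerances: softmax rows and importance sums to 1 within 1e-6/1e-9; TPM/RPM
column sums within 1e-6 relative; Fisher enumeration cutoff 1 + 1e-7
relative.  Degenerate inputs are handled explicitly rather than propagated:
zero-count cells error at normalization, empty QC results warn, tied argmax
and tied markers warn with documented precedence, zero-variance DE genes are
excluded and reported.

## Known limitations

* Models transfer across batches only via zero-imputation of missing genes;
  data from chemistries with very different capture characteristics
  (droplet-based protocols) are out of scope.
* The stage scheme must be total on the training ages; no ordinal or
  regression treatment of age.
* Importance scores rank inputs of one trained model; they are not causal
  effect sizes.
* The architecture is fixed at two hidden layers; only the widths and the
  regularizers are tunable.
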