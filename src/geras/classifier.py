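"""The chronological-stage classifier: a four-layer fully connected network.

Topology is fixed: input layer (one unit per selected gene), two hidden
layers with ReLU activations, and a softmax output layer with one unit per
chronological stage.  Overfitting is controlled by two regularizers tuned
by cross-validation (see :mod:`geras.tuning`):

* dropout on the hidden layers, parameterized as the KEEP probability
  (``dropout=0.8`` keeps 80% of hidden units per training step; 1.0
  disables dropout);
* an L2 penalty ``l2 * sum(W**2)`` over all weight matrices (biases
  unpenalized) added to the mean cross-entropy.

Training uses full-batch Adam, fully seeded, so identical data and seed
reproduce identical weights.  Inputs are log2(x+1)-transformed TPM or RPM
values restricted to the selected gene list; the transform is recorded in
the trained model and re-applied at prediction time.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expr import ExpressionMatrix, log_transform

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Stage scheme
# ---------------------------------------------------------------------------

@dataclass
class StageScheme:
    """Ordered chronological stage labels with an age -> stage mapping.

    ``age_map`` maps exact sampled ages (in ``age_unit``) to stage labels,
    e.g. {1: "Juvenile", 3: "Adolescent", ...} in months post-fertilization.
    """

    stages: tuple
    age_map: dict = field(default_factory=dict)
    age_unit: str = ""

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        if len(self.stages) < 2:
            raise ValueError("need at least two stages")
        for age, stage in self.age_map.items():
            if stage not in self.stages:
                raise ValueError(f"age {age} maps to unknown stage {stage!r}")

    def __len__(self) -> int:
        return len(self.stages)

    def index(self, stage: str) -> int:
        return self.stages.index(stage)

    def stage_of_age(self, age) -> str:
        try:
            return self.age_map[age]
        except KeyError:
            raise KeyError(f"age {age!r} not covered by the stage scheme") from None

    def are_adjacent(self, a: str, b: str) -> bool:
        return abs(self.index(a) - self.index(b)) == 1

    @classmethod
    def zebrafish_beta(cls) -> "StageScheme":
        """Juvenile (1 mpf) < Adolescent (3, 4, 6 mpf) < Adult (10, 12, 14 mpf)."""
        return cls(
            ("Juvenile", "Adolescent", "Adult"),
            {1: "Juvenile", 3: "Adolescent", 4: "Adolescent", 6: "Adolescent",
             10: "Adult", 12: "Adult", 14: "Adult"},
            "mpf",
        )

    @classmethod
    def human_pancreas(cls) -> "StageScheme":
        """Juvenile (0.083, 5, 6 y) < Young (21, 22 y) < Middle (38, 44, 54 y)."""
        return cls(
            ("Juvenile", "Young", "Middle"),
            {0.083: "Juvenile", 5: "Juvenile", 6: "Juvenile",
             21: "Young", 22: "Young",
             38: "Middle", 44: "Middle", 54: "Middle"},
            "years",
        )


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Architecture and training configuration of the stage classifier."""

    n_inputs: int = 1000
    hidden_sizes: tuple = (64, 32)
    dropout: float = 1.0  # keep probability on hidden layers
    l2: float = 0.0
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 400
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if len(self.hidden_sizes) != 2 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("exactly two positive hidden-layer sizes required")
        if not (0 < self.dropout <= 1):
            raise ValueError("dropout keep probability must be in (0, 1]")
        if self.l2 < 0:
            raise ValueError("l2 must be nonnegative")
        if self.n_inputs < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


@dataclass
class TransformSpec:
    """Input transform recorded with a trained model and re-applied at predict."""

    unit: str = "TPM"  # normalization the model expects (TPM or RPM)
    log2: bool = True  # apply log2(x+1) before the network

    def __post_init__(self) -> None:
        if self.unit not in ("TPM", "RPM"):
            raise ValueError("transform unit must be TPM or RPM")


@dataclass
class StageProbabilities:
    """Per-cell softmax probabilities over the stage labels."""

    probs: pd.DataFrame  # index cell_id, columns stage labels

    def __post_init__(self) -> None:
        p = self.probs.to_numpy()
        if (p < 0).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows must be nonnegative and sum to 1")

    @property
    def stages(self) -> tuple:
        return tuple(self.probs.columns)

    def argmax_labels(self, warn_ties: bool = True) -> pd.Series:
        p = self.probs.to_numpy()
        idx = p.argmax(axis=1)  # first maximum = earliest stage on ties
        if warn_ties:
            n_ties = int((np.isclose(p, p.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum())
            if n_ties:
                warnings.warn(
                    f"{n_ties} cell(s) had tied maximal probabilities; "
                    "assigned to the earliest stage",
                    stacklevel=2,
                )
        return pd.Series(
            [self.probs.columns[i] for i in idx], index=self.probs.index, name="predicted_stage"
        )


# ---------------------------------------------------------------------------
# Network internals
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_params(spec: ModelSpec, n_out: int, rng: np.random.Generator) -> dict:
    """He-normal weights, zero biases."""
    sizes = [spec.n_inputs, *spec.hidden_sizes, n_out]
    params = {}
    for i in range(3):
        fan_in = sizes[i]
        params[f"W{i+1}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(sizes[i], sizes[i + 1]))
        params[f"b{i+1}"] = np.zeros(sizes[i + 1])
    return params


def _forward(params: dict, X: np.ndarray, keep: float, rng: np.random.Generator | None):
    """Forward pass; inverted dropout on hidden activations when rng given."""
    cache = {"X": X}
    a = X
    for i in (1, 2):
        z = a @ params[f"W{i}"] + params[f"b{i}"]
        a = np.maximum(z, 0.0)
        cache[f"z{i}"] = z
        if rng is not None and keep < 1.0:
            mask = (rng.random(a.shape) < keep) / keep
            a = a * mask
            cache[f"mask{i}"] = mask
        cache[f"a{i}"] = a
    logits = a @ params["W3"] + params["b3"]
    return logits, cache


def _loss_and_grads(params: dict, cache: dict, logits: np.ndarray, Y: np.ndarray, l2: float):
    n = logits.shape[0]
    P = softmax(logits)
    ce = -np.mean(np.log(np.clip(P[Y.astype(bool)], 1e-300, None)))
    loss = ce + l2 * sum(np.sum(params[f"W{i}"] ** 2) for i in (1, 2, 3))
    dlogits = (P - Y) / n
    grads = {}
    grads["W3"] = cache["a2"].T @ dlogits + 2 * l2 * params["W3"]
    grads["b3"] = dlogits.sum(axis=0)
    da = dlogits @ params["W3"].T
    for i in (2, 1):
        if f"mask{i}" in cache:
            da = da * cache[f"mask{i}"]
        dz = da * (cache[f"z{i}"] > 0)
        prev = cache["X"] if i == 1 else cache["a1"]
        grads[f"W{i}"] = prev.T @ dz + 2 * l2 * params[f"W{i}"]
        grads[f"b{i}"] = dz.sum(axis=0)
        if i == 2:
            da = dz @ params["W2"].T
    return loss, grads


# ---------------------------------------------------------------------------
# Trained model
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted stage classifier: weights, gene list, stages, input transform."""

    spec: ModelSpec
    genes: list
    stages: tuple
    params: dict  # W1,b1,W2,b2,W3,b3
    transform: TransformSpec
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if len(self.genes) != self.spec.n_inputs:
            raise ValueError(
                f"gene list length {len(self.genes)} != n_inputs {self.spec.n_inputs}"
            )
        sizes = [self.spec.n_inputs, *self.spec.hidden_sizes, len(self.stages)]
        for i in range(3):
            w = self.params[f"W{i+1}"]
            if w.shape != (sizes[i], sizes[i + 1]):
                raise ValueError(f"W{i+1} shape {w.shape} inconsistent with spec")
            if not np.all(np.isfinite(w)):
                raise ValueError(f"W{i+1} contains non-finite weights")

    # -- inference -----------------------------------------------------
    def _design_matrix(self, m: ExpressionMatrix) -> np.ndarray:
        if m.unit == "log2":
            mm = m
        elif m.unit == self.transform.unit:
            mm = log_transform(m) if self.transform.log2 else m
        else:
            raise ValueError(
                f"matrix unit {m.unit!r} incompatible with model transform "
                f"({self.transform.unit}, log2={self.transform.log2})"
            )
        return mm.subset_genes(self.genes).values.T  # cells x genes

    def predict_proba(self, m: ExpressionMatrix) -> StageProbabilities:
        X = self._design_matrix(m)
        logits, _ = _forward(self.params, X, keep=1.0, rng=None)
        return StageProbabilities(
            pd.DataFrame(softmax(logits), index=m.cell_ids, columns=list(self.stages))
        )

    def predict_stage(self, m: ExpressionMatrix) -> pd.Series:
        return self.predict_proba(m).argmax_labels()


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def split_train_test(
    m: ExpressionMatrix, stages: pd.Series, train_frac: float = 0.8, seed: int = 0
):
    """Stratified random split of cells into train and test matrices.

    Returns ``(m_train, y_train, m_test, y_test)``; the partition is
    disjoint, exhaustive, stage-stratified and reproducible given the seed.
    """
    from sklearn.model_selection import train_test_split

    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    stages = pd.Series(stages)
    counts = stages.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"stages with < 2 cells cannot be stratified: {small}")
    ids = np.asarray(m.cell_ids)
    tr, te = train_test_split(
        ids, train_size=train_frac, stratify=stages.loc[ids].to_numpy(), random_state=seed
    )
    return (
        m.subset_cells(tr), stages.loc[tr],
        m.subset_cells(te), stages.loc[te],
    )


def build_model(spec: ModelSpec, scheme: StageScheme) -> dict:
    """Seeded initial parameters for the network defined by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    return _init_params(spec, len(scheme), rng)


def train(
    X: np.ndarray,
    y,
    spec: ModelSpec,
    scheme: StageScheme,
    genes,
    transform: TransformSpec | None = None,
    init_params: dict | None = None,
) -> TrainedModel:
    """Fit the network on a cells x genes design matrix ``X`` with stage labels ``y``.

    ``X`` columns must follow the order of ``genes`` (the selected gene
    list), already transformed per ``transform``.  Minimizes mean
    cross-entropy + l2 * sum(W^2) with Adam; dropout masks are redrawn every
    epoch and disabled at inference.
    """
    X = np.asarray(X, dtype=float)
    y = pd.Series(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows and labels differ in length")
    if X.shape[1] != spec.n_inputs:
        raise ValueError(f"X has {X.shape[1]} columns, spec expects {spec.n_inputs}")
    unknown = set(y) - set(scheme.stages)
    if unknown:
        raise ValueError(f"labels outside the stage scheme: {sorted(unknown)}")
    transform = transform or TransformSpec()

    Y = np.zeros((len(y), len(scheme)))
    Y[np.arange(len(y)), [scheme.index(s) for s in y]] = 1.0

    rng = np.random.default_rng(spec.seed)
    params = init_params if init_params is not None else _init_params(spec, len(scheme), rng)
    params = {k: v.copy() for k, v in params.items()}

    # Adam state
    mstate = {k: np.zeros_like(v) for k, v in params.items()}
    vstate = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = spec.learning_rate

    n = X.shape[0]
    batch = spec.batch_size or n
    losses = []
    step = 0
    for epoch in range(spec.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            logits, cache = _forward(params, X[idx], spec.dropout, rng)
            loss, grads = _loss_and_grads(params, cache, logits, Y[idx], spec.l2)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the inputs"
                )
            step += 1
            for k in params:
                mstate[k] = beta1 * mstate[k] + (1 - beta1) * grads[k]
                vstate[k] = beta2 * vstate[k] + (1 - beta2) * grads[k] ** 2
                mhat = mstate[k] / (1 - beta1 ** step)
                vhat = vstate[k] / (1 - beta2 ** step)
                params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)

    return TrainedModel(
        spec=spec,
        genes=list(genes),
        stages=scheme.stages,
        params=params,
        transform=transform,
        loss_history=np.asarray(losses),
    )


def train_on_matrix(
    m: ExpressionMatrix,
    stages: pd.Series,
    genes,
    spec: ModelSpec,
    scheme: StageScheme,
) -> TrainedModel:
    """Convenience wrapper: transform a normalized matrix and fit."""
    transform = TransformSpec(unit=m.unit if m.unit in ("TPM", "RPM") else "TPM")
    mm = log_transform(m) if (transform.log2 and m.unit in ("TPM", "RPM")) else m
    X = mm.subset_genes(genes).values.T
    return train(X, pd.Series(stages).loc[m.cell_ids], spec, scheme, genes, transform)


# ---------------------------------------------------------------------------
# Persistence: single .npz archive with a JSON manifest + weight arrays
# ---------------------------------------------------------------------------

def save_model(tm: TrainedModel, path) -> None:
    manifest = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "spec": asdict(tm.spec),
        "genes": list(tm.genes),
        "stages": list(tm.stages),
        "transform": asdict(tm.transform),
    }
    with open(path, "wb") as fh:  # file handle avoids numpy appending ".npz"
        np.savez(
            fh,
            manifest=np.array(json.dumps(manifest)),
            loss_history=tm.loss_history,
            **tm.params,
        )


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        try:
            manifest = json.loads(str(data["manifest"]))
        except KeyError:
            raise ValueError(f"{path} is not a stage-classifier model file") from None
        if manifest.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {manifest.get('schema_version')!r}"
            )
        spec_d = manifest["spec"]
        spec_d["hidden_sizes"] = tuple(spec_d["hidden_sizes"])
        return TrainedModel(
            spec=ModelSpec(**spec_d),
            genes=manifest["genes"],
            stages=tuple(manifest["stages"]),
            params={k: data[k] for k in ("W1", "b1", "W2", "b2", "W3", "b3")},
            transform=TransformSpec(**manifest["transform"]),
            loss_history=data["loss_history"],
        )


# ---------------------------------------------------------------------------
# Baseline: multinomial logistic regression on the same inputs
# ---------------------------------------------------------------------------

def logistic_baseline_accuracy(
    X_train: np.ndarray, y_train, X_test: np.ndarray, y_test, seed: int = 0
) -> float:
    """Held-out accuracy of a multinomial logistic regression on the same design.

    Serves as the linear reference the network is compared against.
    """
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(X_train, np.asarray(y_train))
    return float(clf.score(X_test, np.asarray(y_test)))
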