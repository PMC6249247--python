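import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import geras

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_synthetic():
    """The default synthetic dataset: 3 stages x 200 cells, 2000 genes."""
    spec = geras.SyntheticSpec(seed=1)
    m, labels, lengths, truth = geras.generate_dataset(spec)
    return spec, m, labels, lengths, truth


@pytest.fixture(scope="session")
def separable_toy():
    """Tiny linearly separable 2-stage dataset: disjoint gene signatures.

    40 cells, 20 per stage; stage A cells express genes 0-4, stage B cells
    genes 5-9, at log2 values around 5 with mild noise.
    """
    rng = np.random.default_rng(0)
    n_genes, n_per = 10, 20
    X = rng.normal(0.0, 0.2, size=(n_genes, 2 * n_per)).clip(0)
    X[:5, :n_per] += 5.0
    X[5:, n_per:] += 5.0
    gene_ids = [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{j}" for j in range(2 * n_per)]
    m = geras.ExpressionMatrix(X, gene_ids, cell_ids, unit="log2")
    labels = pd.Series(["A"] * n_per + ["B"] * n_per, index=cell_ids)
    scheme = geras.StageScheme(("A", "B"))
    return m, labels, scheme


@pytest.fixture(scope="session")
def toy_trained(separable_toy):
    """A model trained to convergence on the separable toy data."""
    m, labels, scheme = separable_toy
    genes = list(m.gene_ids)
    spec = geras.ModelSpec(n_inputs=10, hidden_sizes=(8, 4), dropout=1.0, l2=0.0,
                           epochs=800, seed=0)
    X = m.subset_genes(genes).values.T
    tm = geras.train(X, labels, spec, scheme, genes)
    return tm, m, labels, scheme


@pytest.fixture(scope="session")
def trained_pipeline(default_synthetic):
    """Full pipeline on the default synthetic data: split, tune (2x2), train.

    Session-scoped because several properties (held-out accuracy, adjacent-
    stage behaviour, importance ranking) interrogate the same fitted model.
    """
    spec_s, m, labels, lengths, truth = default_synthetic
    tpm = geras.tpm_normalize(m, lengths)
    genes = geras.select_top_k(geras.rank_genes(tpm), 1000)
    scheme = geras.StageScheme(spec_s.stage_labels)
    m_tr, y_tr, m_te, y_te = geras.split_train_test(tpm, labels, 0.8, seed=1)
    X_tr = geras.log_transform(m_tr).subset_genes(genes).values.T
    base = geras.ModelSpec(epochs=300, seed=1)
    grid = geras.HyperGrid([0.5, 0.8], [0.4, 0.8])
    cv = geras.cross_validate_grid(X_tr, y_tr, grid, base, scheme, seed=1, cv_epochs=100)
    import dataclasses
    tuned = dataclasses.replace(base, dropout=cv.best[0], l2=cv.best[1])
    tm = geras.train(X_tr, y_tr, tuned, scheme, genes,
                     geras.TransformSpec(unit="TPM", log2=True))
    return {
        "spec": spec_s, "lengths": lengths, "truth": truth, "scheme": scheme,
        "genes": genes, "cv": cv, "model": tm,
        "m_test": m_te, "y_test": y_te,
        "m_train": m_tr, "y_train": y_tr,
    }
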