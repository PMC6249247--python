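import dataclasses

import numpy as np
import pandas as pd
import pytest

import geras
from geras.classifier import _forward, build_model


class TestStageScheme:
    def test_zebrafish_scheme_maps_ages(self):
        s = geras.StageScheme.zebrafish_beta()
        assert s.stages == ("Juvenile", "Adolescent", "Adult")
        assert s.stage_of_age(4) == "Adolescent"
        assert s.stage_of_age(14) == "Adult"

    def test_unknown_age_rejected(self):
        with pytest.raises(KeyError):
            geras.StageScheme.zebrafish_beta().stage_of_age(99)

    def test_adjacency(self):
        s = geras.StageScheme.zebrafish_beta()
        assert s.are_adjacent("Juvenile", "Adolescent")
        assert not s.are_adjacent("Juvenile", "Adult")


class TestSplit:
    def _matrix(self, n=100):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 10, size=(5, n))
        m = geras.ExpressionMatrix(vals, [f"g{i}" for i in range(5)],
                                   [f"c{j}" for j in range(n)], unit="log2")
        labels = pd.Series(rng.choice(["A", "B", "C"], n, p=[0.2, 0.3, 0.5]),
                           index=m.cell_ids)
        return m, labels

    def test_cardinality(self):
        m, labels = self._matrix(100)
        tr, ytr, te, yte = geras.split_train_test(m, labels, 0.8, seed=0)
        assert tr.n_cells == 80 and te.n_cells == 20
        assert set(tr.cell_ids) | set(te.cell_ids) == set(m.cell_ids)
        assert not set(tr.cell_ids) & set(te.cell_ids)

    def test_seed_reproducible(self):
        m, labels = self._matrix()
        a = geras.split_train_test(m, labels, 0.8, seed=5)
        b = geras.split_train_test(m, labels, 0.8, seed=5)
        assert list(a[0].cell_ids) == list(b[0].cell_ids)

    def test_stratification_within_one_cell(self):
        m, labels = self._matrix(200)
        tr, ytr, _, _ = geras.split_train_test(m, labels, 0.8, seed=1)
        for stage, total in labels.value_counts().items():
            got = (ytr == stage).sum()
            assert abs(got - 0.8 * total) <= 1

    def test_tiny_stage_rejected(self):
        m, labels = self._matrix(10)
        labels.iloc[0] = "rare"
        labels.iloc[1:] = "common"
        with pytest.raises(ValueError, match="rare"):
            geras.split_train_test(m, labels, 0.8, seed=0)


class TestBuildModel:
    def test_shapes_follow_spec(self):
        spec = geras.ModelSpec(n_inputs=1000, hidden_sizes=(64, 32), seed=3)
        params = build_model(spec, geras.StageScheme(("a", "b", "c")))
        assert params["W1"].shape == (1000, 64)
        assert params["W2"].shape == (64, 32)
        assert params["W3"].shape == (32, 3)

    def test_seeded_init_identical(self):
        spec = geras.ModelSpec(n_inputs=10, hidden_sizes=(4, 3), seed=9)
        scheme = geras.StageScheme(("a", "b"))
        p1, p2 = build_model(spec, scheme), build_model(spec, scheme)
        for k in p1:
            np.testing.assert_array_equal(p1[k], p2[k])

    def test_topology_is_two_hidden_layers(self):
        with pytest.raises(ValueError, match="two positive hidden"):
            geras.ModelSpec(hidden_sizes=(64, 32, 16))


class TestTrain:
    def test_separable_toy_reaches_full_accuracy(self, toy_trained):
        tm, m, labels, scheme = toy_trained
        pred = tm.predict_stage(m)
        assert geras.accuracy(pred, labels) == 1.0
        assert len(tm.loss_history) == 800

    def test_loss_decreases(self, toy_trained):
        tm = toy_trained[0]
        assert tm.loss_history[-1] < tm.loss_history[0]

    def test_regularization_raises_training_loss(self, separable_toy):
        m, labels, scheme = separable_toy
        genes = list(m.gene_ids)
        X = m.subset_genes(genes).values.T
        plain = geras.ModelSpec(n_inputs=10, hidden_sizes=(8, 4), dropout=1.0,
                                l2=0.0, epochs=150, seed=0)
        heavy = dataclasses.replace(plain, l2=1.0, dropout=0.5)
        lm = geras.train(X, labels, plain, scheme, genes)
        hm = geras.train(X, labels, heavy, scheme, genes)
        assert lm.loss_history[-1] < hm.loss_history[-1]

    def test_same_seed_same_weights(self, separable_toy):
        m, labels, scheme = separable_toy
        genes = list(m.gene_ids)
        X = m.subset_genes(genes).values.T
        spec = geras.ModelSpec(n_inputs=10, hidden_sizes=(8, 4), dropout=0.8,
                               l2=0.1, epochs=50, seed=11)
        a = geras.train(X, labels, spec, scheme, genes)
        b = geras.train(X, labels, spec, scheme, genes)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_label_outside_scheme_rejected(self, separable_toy):
        m, labels, scheme = separable_toy
        bad = labels.copy()
        bad.iloc[0] = "Z"
        X = m.values.T
        spec = geras.ModelSpec(n_inputs=10, hidden_sizes=(8, 4), epochs=5, seed=0)
        with pytest.raises(ValueError, match="Z"):
            geras.train(X, bad, spec, scheme, list(m.gene_ids))


class TestPredict:
    def test_zero_weight_model_is_uniform(self):
        spec = geras.ModelSpec(n_inputs=4, hidden_sizes=(3, 2), seed=0)
        params = {k: np.zeros_like(v) for k, v in
                  build_model(spec, geras.StageScheme(("a", "b", "c"))).items()}
        tm = geras.TrainedModel(spec, ["g0", "g1", "g2", "g3"], ("a", "b", "c"),
                                params, geras.TransformSpec())
        m = geras.ExpressionMatrix(np.random.default_rng(0).uniform(0, 5, (4, 6)),
                                   [f"g{i}" for i in range(4)],
                                   [f"c{j}" for j in range(6)], unit="log2")
        probs = tm.predict_proba(m).probs.to_numpy()
        np.testing.assert_allclose(probs, 1 / 3, atol=1e-12)

    def test_rows_sum_to_one(self, toy_trained):
        tm, m, _, _ = toy_trained
        p = tm.predict_proba(m).probs.to_numpy()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_confident_on_separable_fixture(self, toy_trained):
        tm, m, labels, _ = toy_trained
        probs = tm.predict_proba(m).probs
        for cid, stage in labels.items():
            assert probs.loc[cid, stage] >= 0.99

    def test_permuting_cells_permutes_predictions(self, toy_trained):
        tm, m, _, _ = toy_trained
        perm = np.random.default_rng(1).permutation(m.n_cells)
        m2 = m.subset_cells(np.asarray(m.cell_ids)[perm])
        p1 = tm.predict_proba(m).probs
        p2 = tm.predict_proba(m2).probs
        pd.testing.assert_frame_equal(p1.loc[p2.index], p2)

    def test_argmax_and_tie_rule(self):
        probs = geras.StageProbabilities(pd.DataFrame(
            [[0.1, 0.7, 0.2], [0.5, 0.5, 0.0]],
            index=["c1", "c2"], columns=["a", "b", "c"]))
        with pytest.warns(UserWarning, match="tied"):
            labels = probs.argmax_labels()
        assert labels["c1"] == "b"
        assert labels["c2"] == "a"  # tie broken toward earlier stage

    def test_predict_stage_matches_argmax(self, toy_trained):
        tm, m, _, _ = toy_trained
        pd.testing.assert_series_equal(
            tm.predict_stage(m),
            tm.predict_proba(m).argmax_labels(warn_ties=False),
        )

    def test_unit_mismatch_rejected(self, toy_trained):
        tm = toy_trained[0]  # expects TPM input
        vals = np.random.default_rng(0).poisson(5, (10, 3)).astype(float)
        vals = vals / vals.sum(0) * 1e6
        m = geras.ExpressionMatrix(vals, [f"g{i}" for i in range(10)],
                                   ["x", "y", "z"], unit="RPM")
        tm_rpm_free = dataclasses.replace(tm)  # default transform unit is TPM
        with pytest.raises(ValueError, match="incompatible"):
            tm_rpm_free.predict_proba(m)

    def test_missing_genes_imputed_as_zero(self, toy_trained):
        tm, m, labels, _ = toy_trained
        # drop the last gene: predictions still computable
        sub = geras.ExpressionMatrix(m.values[:-1], m.gene_ids[:-1], m.cell_ids,
                                     unit="log2")
        p = tm.predict_proba(sub).probs.to_numpy()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestPersistence:
    def test_round_trip_identical_predictions(self, toy_trained, tmp_path):
        tm, m, _, _ = toy_trained
        path = tmp_path / "model.geras"
        geras.save_model(tm, path)
        back = geras.load_model(path)
        assert back.genes == tm.genes
        np.testing.assert_array_equal(
            back.predict_proba(m).probs.to_numpy(),
            tm.predict_proba(m).probs.to_numpy())

    def test_wrong_schema_rejected(self, toy_trained, tmp_path):
        import json
        tm = toy_trained[0]
        path = tmp_path / "model.geras"
        geras.save_model(tm, path)
        # corrupt the schema version
        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files}
        manifest = json.loads(str(arrays["manifest"]))
        manifest["schema_version"] = 999
        arrays["manifest"] = np.array(json.dumps(manifest))
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)
        with pytest.raises(ValueError, match="schema version"):
            geras.load_model(path)

    def test_non_model_file_rejected(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, x=np.arange(3))
        with pytest.raises(ValueError, match="not a stage-classifier"):
            geras.load_model(path)


class TestSoftmax:
    def test_rows_sum_to_one_for_arbitrary_logits(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(0, 50, size=(100, 4))
        logits[0] = [1e300, -1e300, 0, 0][:4]  # extreme but finite
        p = geras.softmax(logits)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()
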