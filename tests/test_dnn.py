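import numpy as np
import pytest

import emgmotion as em
from emgmotion.dnn import MLPNetwork, parameter_count
from emgmotion.errors import InputError


def feature_table(values, labels):
    values = np.asarray(values, float)
    return em.FeatureTable(
        values=values,
        names=[f"f{i}" for i in range(values.shape[1])],
        labels=np.asarray(labels, int),
        repetitions=np.zeros(len(values), int),
        threshold_used=0.0,
    )


def separable_table(n_per_class=60, n_classes=3, dim=6, seed=0, spread=0.05):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 3, size=(n_classes, dim))
    values = np.vstack(
        [centers[k] + rng.normal(0, spread, size=(n_per_class, dim)) for k in range(n_classes)]
    )
    labels = np.repeat(np.arange(n_classes), n_per_class)
    return feature_table(values, labels)


class TestBuild:
    def test_closed_form_parameter_count(self):
        spec = em.ClassifierSpec(n_classes=42, seed=0)
        # independent arithmetic: dense + batch-norm(gamma, beta) per hidden
        expected = (
            (96 * 512 + 512) + 2 * 512
            + (512 * 256 + 256) + 2 * 256
            + (256 * 256 + 256) + 2 * 256
            + (256 * 42 + 42)
        )
        assert parameter_count(spec, input_dim=96) == expected
        net = em.build(spec, input_dim=96)
        introspected = sum(
            layer[k].size for layer in net.hidden for k in ("W", "b", "gamma", "beta")
        ) + net.out["W"].size + net.out["b"].size
        assert introspected == expected

    def test_seeded_init_determinism(self):
        spec = em.ClassifierSpec(n_classes=3, seed=9)
        a, b = em.build(spec, 12), em.build(spec, 12)
        for la, lb in zip(a.hidden, b.hidden):
            np.testing.assert_array_equal(la["W"], lb["W"])
        np.testing.assert_array_equal(a.out["W"], b.out["W"])

    def test_he_uniform_bounds(self):
        net = em.build(em.ClassifierSpec(n_classes=2, seed=0), 100)
        limit = np.sqrt(6.0 / 100)
        assert np.all(np.abs(net.hidden[0]["W"]) <= limit)

    def test_untrained_forward_is_probability_vector(self):
        net = em.build(em.ClassifierSpec(n_classes=5, seed=1), 8)
        probs, _ = net.forward(np.zeros((3, 8)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs > 0)


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(em.softmax_probabilities([0.0, 0.0]), [0.5, 0.5])

    def test_closed_form(self):
        np.testing.assert_allclose(
            em.softmax_probabilities([np.log(2), 0.0]), [2 / 3, 1 / 3], rtol=1e-12
        )

    def test_shift_invariance(self):
        z = np.array([0.3, -1.2, 4.0])
        np.testing.assert_allclose(
            em.softmax_probabilities(z), em.softmax_probabilities(z + 123.0), atol=1e-12
        )

    def test_non_finite_rejected(self):
        with pytest.raises(InputError):
            em.softmax_probabilities([np.inf, 0.0])

    def test_rows_sum_to_one_on_random_matrices(self):
        rng = np.random.default_rng(3)
        p = em.softmax_probabilities(rng.normal(0, 10, size=(50, 7)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((p > 0) & (p < 1))


class TestCrossEntropy:
    def test_closed_form(self):
        assert em.cross_entropy([[0.5, 0.5]], [[1, 0]]) == pytest.approx(np.log(2))

    def test_perfect_prediction(self):
        assert em.cross_entropy([[1.0, 0.0]], [[1, 0]]) == pytest.approx(0.0)

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(20, 4))
        p = em.softmax_probabilities(logits)
        t = np.eye(4)[rng.integers(0, 4, 20)]
        assert em.cross_entropy(p, t) >= 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            em.cross_entropy([[0.5, 0.5]], [[1, 0, 0]])


class TestTrain:
    def test_separable_data_high_training_accuracy(self):
        table = separable_table(seed=1)
        model = em.train(table, epochs=30, batch_size=32, seed=2)
        y_pred = model.classify_table(table)
        report = em.evaluate_predictions(table.labels, y_pred, model.class_list)
        assert report.macro_recall >= 99.0

    def test_seeded_training_determinism(self):
        table = separable_table(seed=5)
        a = em.train(table, epochs=5, batch_size=32, seed=3)
        b = em.train(table, epochs=5, batch_size=32, seed=3)
        for la, lb in zip(a.network.hidden, b.network.hidden):
            np.testing.assert_array_equal(la["W"], lb["W"])
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)

    def test_loss_trace_sanity(self):
        table = separable_table(seed=6)
        model = em.train(table, epochs=10, batch_size=32, seed=1)
        assert np.all(np.isfinite(model.loss_trace))
        assert model.loss_trace.min() <= model.loss_trace[0]

    def test_single_class_rejected(self):
        table = feature_table(np.random.default_rng(0).normal(size=(10, 4)), np.zeros(10))
        with pytest.raises(InputError):
            em.train(table, epochs=1)

    def test_internal_standardizer_flagged(self):
        table = separable_table(seed=7)
        model = em.train(table, epochs=2, batch_size=64, seed=0)
        assert model.meta["standardizer_fit"] == "internal"
        assert model.standardizer is not None


class TestPredict:
    def test_predict_matches_argmax_of_proba(self):
        table = separable_table(seed=8)
        model = em.train(table, epochs=5, batch_size=32, seed=4)
        X = em.apply_standardizer(model.standardizer, table).values
        probs = model.predict_proba(X)
        np.testing.assert_array_equal(model.predict(X), model.class_list[np.argmax(probs, axis=1)])

    def test_exact_tie_goes_to_lower_class_index(self):
        """Zeroed output weights give identical logits: a genuine tie."""
        spec = em.ClassifierSpec(n_classes=2, hidden_widths=(4,), epochs=1, seed=0)
        net = MLPNetwork(spec, 3, np.random.default_rng(0))
        net.out["W"][:] = 0.0
        net.out["b"][:] = 0.0
        model = em.TrainedClassifier(
            spec=spec,
            network=net,
            class_list=np.array([2, 7]),
            standardizer=None,
            loss_trace=np.zeros(1),
        )
        probs = model.predict_proba(np.ones((1, 3)))
        np.testing.assert_allclose(probs, [[0.5, 0.5]])
        assert model.predict(np.ones((1, 3)))[0] == 2

    def test_dimension_mismatch_rejected(self):
        table = separable_table(seed=9)
        model = em.train(table, epochs=1, batch_size=64, seed=0)
        with pytest.raises(InputError):
            model.predict(np.zeros((2, 99)))


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        table = separable_table(seed=10)
        model = em.train(table, epochs=5, batch_size=32, seed=6)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = em.TrainedClassifier.load(path)
        X = em.apply_standardizer(model.standardizer, table).values
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))
        np.testing.assert_allclose(loaded.predict_proba(X), model.predict_proba(X), atol=1e-12)
        assert loaded.spec == model.spec
        np.testing.assert_array_equal(loaded.class_list, model.class_list)
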