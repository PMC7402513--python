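import numpy as np
import pytest

from sidefx.classify import (
    ClassifierSpec,
    TrainingSet,
    backend_fit_predict,
    build_training_set,
    elm_fit,
    elm_predict,
    fit_predict,
    knn_fit_predict,
    register_backend,
    vectorize,
)
from sidefx.negatives import select_reliable_negatives

from conftest import make_scored_dataset


def toy_training_set(n_per_class=10, margin=5.0, seed=0):
    """Two well-separated Gaussian blobs in the plane (linearly separable)."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(loc=(+margin, 0.0), scale=0.3, size=(n_per_class, 2))
    neg = rng.normal(loc=(-margin, 0.0), scale=0.3, size=(n_per_class, 2))
    # exhaustive separability check: every positive x-coordinate above every negative
    assert pos[:, 0].min() > neg[:, 0].max()
    return TrainingSet(
        side_effect_id="SE0",
        X_pos=pos,
        X_neg=neg,
        pos_ids=[f"P{i}" for i in range(n_per_class)],
        neg_ids=[f"N{i}" for i in range(n_per_class)],
        balance_mode="balanced",
        n_s=n_per_class,
    )


class TestVectorize:
    def test_vector_is_matrix_row_with_unit_self_entry(self, bench_dataset, bench_S):
        d = bench_dataset.drug_ids[5]
        v = vectorize(d, bench_S)
        np.testing.assert_array_equal(v, bench_S.values[5])
        assert v[5] == 1.0
        assert len(v) == bench_dataset.n_drugs

    def test_unknown_drug_raises(self, bench_S):
        with pytest.raises(KeyError):
            vectorize("NOPE", bench_S)


class TestBuildTrainingSet:
    def _world(self, n_pos, n_cand):
        scores = {f"C{i:02d}": 0.1 * (i % 7) for i in range(n_cand)}
        positives = [f"P{i:02d}" for i in range(n_pos)]
        return make_scored_dataset(scores, positives=positives)

    def test_balanced_min_rule_small_positive_side(self):
        ds, S = self._world(10, 40)
        gold = select_reliable_negatives(ds, "SE0", S, n=10)
        ts = build_training_set(ds, "SE0", S, gold, balance="balanced", seed=0)
        assert ts.n_s == 10
        assert len(ts.pos_ids) == len(ts.neg_ids) == 10

    def test_balanced_min_rule_small_unlabeled_side(self):
        ds, S = self._world(30, 20)
        gold = select_reliable_negatives(ds, "SE0", S, n=20)
        ts = build_training_set(ds, "SE0", S, gold, balance="balanced", seed=0)
        assert ts.n_s == 20
        assert len(ts.pos_ids) == 20  # seeded subsample of the 30 labeled drugs
        ts2 = build_training_set(ds, "SE0", S, gold, balance="balanced", seed=0)
        assert ts.pos_ids == ts2.pos_ids

    def test_unbalanced_uses_everything(self):
        ds, S = self._world(10, 40)
        ts = build_training_set(ds, "SE0", S, None, balance="unbalanced")
        assert len(ts.pos_ids) == 10
        assert len(ts.neg_ids) == 40


class TestKNN:
    def test_test_point_identical_to_positive_with_k1(self):
        ts = toy_training_set()
        scores, labels = knn_fit_predict(ts, ts.X_pos[:1], k=1)
        assert scores[0] == 1.0 and labels[0] == 1

    def test_k_at_least_training_size_gives_global_vote(self):
        ts = toy_training_set(n_per_class=4)
        scores, _ = knn_fit_predict(ts, np.array([[100.0, 100.0]]), k=999)
        assert scores[0] == pytest.approx(0.5)

    def test_scores_match_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(5, 3))
        ts = TrainingSet("SE0", X[:2], X[2:], ["A", "B"], ["C", "D", "E"], "cv-train", 2)
        tests = rng.normal(size=(7, 3))
        k = 3
        scores, _ = knn_fit_predict(ts, tests, k=k)
        ids = ["A", "B", "C", "D", "E"]
        y = [1, 1, 0, 0, 0]
        for i, t in enumerate(tests):
            dists = [float(np.linalg.norm(t - x)) for x in np.vstack([X[:2], X[2:]])]
            order = sorted(range(5), key=lambda j: (round(dists[j] ** 2, 12), ids[j]))
            expected = sum(y[j] for j in order[:k]) / k
            assert scores[i] == pytest.approx(expected)

    def test_score_granularity(self):
        ts = toy_training_set(n_per_class=3)
        scores, _ = knn_fit_predict(ts, ts.X, k=4)
        for s in scores:
            assert round(s * 4, 9) == int(round(s * 4))

    def test_empty_training_set_raises(self):
        ts = TrainingSet("SE0", np.empty((0, 2)), np.empty((0, 2)), [], [], "cv-train", 0)
        with pytest.raises(ValueError):
            knn_fit_predict(ts, np.zeros((1, 2)), k=1)


class TestELM:
    def test_separable_toy_set_interpolated(self):
        ts = toy_training_set(n_per_class=10)
        model = elm_fit(ts, hidden_units=50, seed=0)
        _, labels = elm_predict(model, ts.X)
        np.testing.assert_array_equal(labels, ts.y.astype(int))

    def test_same_seed_identical_model_and_predictions(self):
        ts = toy_training_set()
        m1 = elm_fit(ts, hidden_units=20, seed=5)
        m2 = elm_fit(ts, hidden_units=20, seed=5)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.beta, m2.beta)
        s1, l1 = elm_predict(m1, ts.X)
        s2, l2 = elm_predict(m2, ts.X)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(l1, l2)

    def test_constant_label_training_predicts_that_label(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 2))
        ts = TrainingSet("SE0", X, np.empty((0, 2)), [f"P{i}" for i in range(8)], [], "cv-train", 0)
        model = elm_fit(ts, hidden_units=10, seed=0)
        _, labels = elm_predict(model, rng.normal(size=(5, 2)))
        assert (labels == 1).all()

    def test_interpolation_with_ample_hidden_units(self):
        """hidden_units >= n_train on distinct inputs -> zero training error."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 4))
        y_pos, y_neg = X[:6], X[6:]
        ts = TrainingSet(
            "SE0", y_pos, y_neg,
            [f"P{i}" for i in range(6)], [f"N{i}" for i in range(6)], "cv-train", 6,
        )
        model = elm_fit(ts, hidden_units=64, seed=1)
        _, labels = elm_predict(model, ts.X)
        np.testing.assert_array_equal(labels, ts.y.astype(int))


class TestBackends:
    def test_svm_separable_training_accuracy(self):
        ts = toy_training_set()
        spec = ClassifierSpec(kind="svm", gamma=0.07)
        _, labels = backend_fit_predict(spec, ts, ts.X)
        np.testing.assert_array_equal(labels, ts.y.astype(int))

    def test_rbf_separable_training_accuracy(self):
        ts = toy_training_set()
        spec = ClassifierSpec(kind="rbf", spread=500.0)
        _, labels = backend_fit_predict(spec, ts, ts.X)
        np.testing.assert_array_equal(labels, ts.y.astype(int))

    def test_native_kinds_not_routed_to_backend(self):
        ts = toy_training_set()
        with pytest.raises(ValueError, match="natively"):
            backend_fit_predict(ClassifierSpec(kind="knn"), ts, ts.X)

    def test_unregistered_kind_gives_capability_error(self):
        ts = toy_training_set()
        with pytest.raises(NotImplementedError, match="no backend registered"):
            backend_fit_predict(ClassifierSpec(kind="deep"), ts, ts.X)

    def test_backend_calls_are_deterministic(self):
        ts = toy_training_set()
        for kind in ("svm", "rbf"):
            spec = ClassifierSpec(kind=kind, seed=3)
            s1, l1 = backend_fit_predict(spec, ts, ts.X)
            s2, l2 = backend_fit_predict(spec, ts, ts.X)
            np.testing.assert_array_equal(s1, s2)
            np.testing.assert_array_equal(l1, l2)

    def test_custom_backend_registration(self):
        def constant_backend(spec, train, X_test):
            return np.zeros(len(X_test)), np.zeros(len(X_test), dtype=int)

        register_backend("const", constant_backend)
        ts = toy_training_set()
        scores, labels = fit_predict(ClassifierSpec(kind="const"), ts, ts.X)
        assert (labels == 0).all()
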