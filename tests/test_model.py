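"""Classifier mechanics: loss, optimizer, gradients, invariances, training."""

import numpy as np
import pytest

import gsfan.model as gm
from gsfan.graph import knn_neighbors
from gsfan.hand import generate_dataset
from gsfan.io import normalize_cloud, split_dataset
from gsfan.layers import aggregation_matrix
from gsfan.model import (
    GSFANClassifier,
    ModelConfig,
    TrainConfig,
    backward,
    cross_entropy_loss,
    forward,
    init_params,
    load_model,
    save_model,
    sgd_momentum_step,
    train,
)


class TestCrossEntropy:
    def test_uniform_logits_give_ln_n_classes(self):
        scores = np.zeros((4, 32))
        loss, _ = cross_entropy_loss(scores, [0, 5, 17, 31])
        assert loss == pytest.approx(np.log(32), abs=1e-12)

    def test_dominant_true_score_drives_loss_to_zero(self):
        scores = np.zeros((1, 8))
        scores[0, 3] = 1e4
        loss, _ = cross_entropy_loss(scores, [3])
        assert loss < 1e-8

    def test_matches_direct_softmax_oracle(self, rng):
        scores = rng.normal(size=(6, 5))
        labels = rng.integers(0, 5, size=6)
        loss, dscores = cross_entropy_loss(scores, labels)
        expected = 0.0
        for r in range(6):
            p = np.exp(scores[r]) / np.exp(scores[r]).sum()
            expected -= np.log(p[labels[r]])
        assert loss == pytest.approx(expected / 6, rel=1e-12)
        # gradient rows sum to zero (softmax minus one-hot)
        np.testing.assert_allclose(dscores.sum(axis=1), 0.0, atol=1e-12)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros((2, 4)), [0, 4])


class TestSGDMomentum:
    def test_zero_momentum_is_plain_gradient_descent(self, rng):
        p = rng.normal(size=(3, 3))
        g = rng.normal(size=(3, 3))
        p2, v2 = sgd_momentum_step(p, g, np.zeros_like(p), lr=0.1, momentum=0.0)
        np.testing.assert_allclose(p2, p - 0.1 * g, atol=1e-12)
        np.testing.assert_allclose(v2, -0.1 * g, atol=1e-12)

    def test_zero_gradient_decays_velocity_geometrically(self, rng):
        v = rng.normal(size=4)
        p = np.zeros(4)
        for step in range(3):
            p, v_new = sgd_momentum_step(p, np.zeros(4), v, lr=0.1, momentum=0.9)
            np.testing.assert_allclose(v_new, v * 0.9, atol=1e-12)
            v = v_new

    def test_two_constant_gradient_steps_match_closed_form(self, rng):
        g = rng.normal(size=5)
        p0 = rng.normal(size=5)
        lr, m = 0.01, 0.9
        p, v = sgd_momentum_step(p0, g, np.zeros(5), lr, m)
        p, v = sgd_momentum_step(p, g, v, lr, m)
        np.testing.assert_allclose(p, p0 - lr * g * (2 + m), atol=1e-12)

    def test_dict_form_updates_every_key(self, rng):
        params = {"a": rng.normal(size=2), "b": rng.normal(size=(2, 2))}
        grads = {k: np.ones_like(v) for k, v in params.items()}
        vel = {k: np.zeros_like(v) for k, v in params.items()}
        p2, v2 = sgd_momentum_step(params, grads, vel, 0.5, 0.0)
        for k in params:
            np.testing.assert_allclose(p2[k], params[k] - 0.5, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sgd_momentum_step(np.zeros(3), np.zeros(4), np.zeros(3), 0.1, 0.9)


def _prep_batch(coords_list, k):
    mats, norms = [], []
    for c in coords_list:
        norm = normalize_cloud(c)
        norms.append(norm)
        mats.append(aggregation_matrix(knn_neighbors(norm, k)))
    return np.stack(norms), mats


class TestGradients:
    @pytest.mark.parametrize("gate_location,pool", [
        ("global", "max"), ("per_point", "max"), ("global", "mean"),
    ])
    def test_backward_matches_numerical_gradient(self, rng, monkeypatch,
                                                 gate_location, pool):
        monkeypatch.setattr(gm, "_DTYPE", np.float64)
        config = ModelConfig(
            n_edgeconv_layers=2, k=3, edgeconv_dims=(5, 6), target_dim=7,
            hidden_dim=5, dropout_rate=0.0, n_classes=4,
            gate_location=gate_location, pool=pool,
        )
        coords_list = [rng.random((12, 3)) for _ in range(3)]
        coords, mats = _prep_batch(coords_list, config.k)
        params = init_params(config, rng)
        labels = np.array([0, 2, 3])

        def loss_fn():
            scores, _ = forward(coords, mats, params, config)
            return cross_entropy_loss(scores, labels)[0]

        scores, cache = forward(coords, mats, params, config)
        _, dscores = cross_entropy_loss(scores, labels)
        grads = backward(dscores, cache, params, config)

        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for key, p in params.items():
            flat = p.ravel()
            picks = check_rng.choice(flat.size, size=min(4, flat.size), replace=False)
            for idx in picks:
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_fn()
                flat[idx] = orig - eps
                down = loss_fn()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[key].ravel()[idx]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7), key


@pytest.fixture(scope="module")
def fitted_stub():
    """Classifier with initialized (untrained) parameters on 32 classes."""
    rng = np.random.default_rng(3)
    clouds = [rng.random((24, 3)) for _ in range(32)]
    clf = GSFANClassifier(epochs=0, random_state=1)
    clf.fit(clouds, np.arange(32))
    return clf


class TestForwardInvariances:
    def test_scores_have_32_classes(self, fitted_stub, rng):
        scores = fitted_stub.decision_function([rng.random((20, 3))])
        assert scores.shape == (1, 32)

    def test_point_permutation_leaves_scores_unchanged(self, fitted_stub, rng):
        cloud = rng.random((30, 3))
        permuted = cloud[rng.permutation(30)]
        a = fitted_stub.decision_function([cloud])
        b = fitted_stub.decision_function([permuted])
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_duplicated_cloud_gives_identical_rows(self, fitted_stub, rng):
        cloud = rng.random((20, 3))
        scores = fitted_stub.decision_function([cloud, cloud])
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_cloud_smaller_than_k_rejected(self, fitted_stub, rng):
        with pytest.raises(ValueError):
            fitted_stub.decision_function([rng.random((8, 3))])

    def test_predict_breaks_ties_toward_lowest_class(self, fitted_stub):
        scores = np.zeros((1, 32), dtype=np.float32)
        scores[0, 3] = scores[0, 7] = 5.0
        fitted_stub_clone = GSFANClassifier()
        fitted_stub_clone.classes_ = np.arange(32)
        fitted_stub_clone.params_ = fitted_stub.params_
        fitted_stub_clone.config_ = fitted_stub.config_
        fitted_stub_clone.decision_function = lambda X: scores
        assert fitted_stub_clone.predict([None]) == [3]


class TestTraining:
    def test_same_seed_gives_identical_history_and_params(self, tiny_dataset):
        X = [c.coords for c in tiny_dataset]
        y = [c.label for c in tiny_dataset]
        a = GSFANClassifier(epochs=2, target_dim=16, random_state=5).fit(X, y)
        b = GSFANClassifier(epochs=2, target_dim=16, random_state=5).fit(X, y)
        np.testing.assert_array_equal(a.history_.loss, b.history_.loss)
        for k in a.params_:
            np.testing.assert_array_equal(a.params_[k], b.params_[k])

    def test_zero_learning_rate_freezes_parameters(self, tiny_dataset):
        X = [c.coords for c in tiny_dataset]
        y = [c.label for c in tiny_dataset]
        clf = GSFANClassifier(epochs=3, target_dim=16, learning_rate=0.0,
                              dropout_rate=0.0, random_state=2).fit(X, y)
        rng = np.random.default_rng(2)
        reference = gm.init_params(clf.config_, rng)
        for k in clf.params_:
            np.testing.assert_array_equal(clf.params_[k], reference[k])
        np.testing.assert_allclose(clf.history_.loss, clf.history_.loss.iloc[0],
                                   atol=1e-6)

    def test_two_cloud_memorization(self, rng):
        clouds = [rng.random((24, 3)), rng.random((24, 3)) + 2.0]
        labels = [0, 1]
        clf = GSFANClassifier(epochs=40, learning_rate=0.05, dropout_rate=0.0,
                              target_dim=16, batch_size=2, random_state=0)
        clf.fit(clouds, labels)
        assert list(clf.predict(clouds)) == labels

    def test_train_wrapper_and_persistence_round_trip(self, tiny_dataset, tmp_path):
        split = split_dataset(tiny_dataset, 0.75, seed=0)
        mc = ModelConfig(target_dim=16)
        tc = TrainConfig(epochs=1, seed=1)
        clf, history = train(split, mc, tc)
        assert len(history) == 1
        path = tmp_path / "model.npz"
        save_model(clf, path)
        loaded = load_model(path)
        X = [c.coords for c in split.test]
        np.testing.assert_allclose(
            clf.decision_function(X), loaded.decision_function(X), atol=1e-6
        )

    def test_empty_training_set_rejected(self):
        from gsfan.io import DatasetSplit

        with pytest.raises(ValueError):
            train(DatasetSplit([], [], 0.5, 0), ModelConfig(), TrainConfig(epochs=1))
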