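"""3D CNN: shape arithmetic, sparse-vs-dense oracle, gradients, training."""

import numpy as np
import pytest

from lesion2score import generate_lesion
from lesion2score.cnn import (
    CNNConfig,
    CNNResults,
    POOLED_SHAPE,
    ScoreScaler,
    SparseLesionPatch,
    _Weights,
    _backward,
    _forward,
    _init_weights,
    cnn_forward,
    extract_cnn_features,
    fit_cnn,
    forward_dense,
)
from lesion2score.exceptions import GridError, StateError, ValidationError
from lesion2score.imaging import GRID_SHAPE


def random_weights(seed, nonzero_bias=True):
    rng = np.random.default_rng(seed)
    W = _init_weights(CNNConfig(seed=seed), rng)
    if nonzero_bias:
        W.bc = rng.normal(0, 0.5, 4).astype(np.float32)
    return W


class TestShapeArithmetic:
    def test_pooled_maps_are_8x10x8_per_kernel(self):
        """ceil-mode 8^3 pooling of the same-padded 61x73x61 conv output."""
        assert POOLED_SHAPE == (8, 10, 8)
        W = random_weights(0)
        im = generate_lesion(1, (30, 36, 30), 200)
        _, pooled, _ = forward_dense(W, im.voxels)
        assert pooled.shape == (8, 10, 8, 4)

    def test_conv_layer_has_112_trainable_parameters(self):
        cfg = CNNConfig()
        assert cfg.n_conv_params == 4 * 27 + 4 == 112
        W = random_weights(1)
        assert W.Wc.size + W.bc.size == 112

    def test_output_strictly_in_unit_interval(self):
        W = random_weights(2)
        for seed in range(3):
            im = generate_lesion(seed, (20, 30, 20), 150)
            out, _ = _forward(SparseLesionPatch.from_image(im), W)
            assert 0.0 < out < 1.0

    def test_zero_weights_zero_input_gives_half(self):
        cfg = CNNConfig()
        W = _Weights(
            Wc=np.zeros((4, 27), np.float32), bc=np.zeros(4, np.float32),
            W1=np.zeros((cfg.n_flat_features, 500), np.float32),
            b1=np.zeros(500, np.float32), w2=np.zeros(500, np.float32), b2=0.0,
        )
        out, _, _ = forward_dense(W, np.zeros(GRID_SHAPE))
        assert out == pytest.approx(0.5)

    def test_wrong_input_shape_rejected(self):
        W = random_weights(3)
        with pytest.raises(GridError):
            forward_dense(W, np.zeros((10, 10, 10)))


class TestSparseDenseEquivalence:
    @pytest.mark.parametrize("seed,centroid,volume", [
        (1, (30, 36, 30), 1),
        (2, (13, 29, 33), 500),
        (3, (5, 5, 5), 2000),      # bounding box clipped at the grid corner
        (4, (58, 70, 58), 50),     # partial pooling windows at the far faces
    ])
    def test_sparse_path_matches_dense_reference(self, seed, centroid, volume):
        """The bounding-box fast path must reproduce the dense scipy forward
        pass exactly (same pooled maps, same output)."""
        W = random_weights(10 + seed)
        im = generate_lesion(seed, centroid, volume)
        out_s, cache = _forward(SparseLesionPatch.from_image(im), W)
        out_d, pooled_d, h_d = forward_dense(W, im.voxels)
        assert np.allclose(cache["pooled"].reshape(-1), pooled_d.reshape(-1), atol=2e-5)
        assert out_s == pytest.approx(out_d, abs=1e-6)

    def test_gradients_match_finite_differences(self):
        W = random_weights(20)
        im = generate_lesion(5, (13, 29, 33), 300)
        patch = SparseLesionPatch.from_image(im)
        target = 0.3
        grads = _Weights(*(np.zeros_like(getattr(W, f)) for f in
                           ("Wc", "bc", "W1", "b1", "w2")), 0.0)
        out, cache = _forward(patch, W)
        _backward(patch, W, cache, out, 2 * (out - target), grads)
        eps = 1e-3
        for fname, idx in [("Wc", (1, 13)), ("bc", (2,)), ("W1", (100, 7)), ("w2", (11,))]:
            num = []
            for sign in (+1, -1):
                W2 = W.copy()
                arr = getattr(W2, fname).astype(np.float64)
                arr[idx] += sign * eps
                setattr(W2, fname, arr.astype(np.float32))
                o, _ = _forward(patch, W2)
                num.append((o - target) ** 2)
            fd = (num[0] - num[1]) / (2 * eps)
            assert getattr(grads, fname)[idx] == pytest.approx(fd, abs=2e-3)


class TestScoreScaler:
    def test_roundtrip_within_fitted_range(self):
        scores = np.array([-8.0, -1.5, 0.0, 2.0, 4.5])
        sc = ScoreScaler.fit(scores)
        assert np.allclose(sc.inverse(sc.forward(scores)), scores, atol=1e-10)
        assert sc.forward(scores).min() == pytest.approx(0.1)
        assert sc.forward(scores).max() == pytest.approx(0.9)

    def test_inverse_clips_saturated_outputs(self):
        sc = ScoreScaler.fit(np.array([-1.0, 1.0]))
        assert sc.inverse(0.99) == pytest.approx(1.0)
        assert sc.inverse(0.01) == pytest.approx(-1.0)

    def test_degenerate_scores_give_constant_predictor(self):
        sc = ScoreScaler.fit(np.array([2.0, 2.0, 2.0]))
        assert sc.degenerate
        assert np.allclose(sc.forward([2.0, 2.0]), 0.5)
        assert sc.inverse(0.77) == pytest.approx(2.0)


class TestTraining:
    @pytest.fixture(scope="class")
    def toy_training(self):
        images = [generate_lesion(10 + i, (13 + i % 5, 25 + i % 7, 30 + i % 5),
                                  50 + 37 * i) for i in range(20)]
        scores = np.array([2.0 - im.volume / 2000.0 for im in images])
        return images, scores

    def test_training_decreases_mse(self, toy_training):
        images, scores = toy_training
        res = fit_cnn(images, scores, CNNConfig(epochs=5, batch_size=8, seed=42))
        assert res.final_loss < res.initial_loss

    def test_same_seed_gives_identical_weights(self, toy_training):
        images, scores = toy_training
        cfg = CNNConfig(epochs=2, batch_size=8, seed=3)
        r1 = fit_cnn(images, scores, cfg)
        r2 = fit_cnn(images, scores, cfg)
        for f in ("Wc", "bc", "W1", "b1", "w2"):
            assert (getattr(r1.weights, f) == getattr(r2.weights, f)).all()
        assert r1.weights.b2 == r2.weights.b2

    def test_predictions_within_scaler_range(self, toy_training):
        images, scores = toy_training
        res = fit_cnn(images, scores, CNNConfig(epochs=2, seed=1))
        preds = res.predict(images[:5])
        assert (preds >= scores.min() - 1e-9).all()
        assert (preds <= scores.max() + 1e-9).all()

    def test_degenerate_scores_trained_as_constant(self, toy_training):
        images, _ = toy_training
        res = fit_cnn(images[:4], np.full(4, 1.5), CNNConfig(epochs=2, seed=0))
        assert np.allclose(res.predict(images[:2]), 1.5)

    def test_needs_two_pairs(self):
        with pytest.raises(ValidationError):
            fit_cnn([generate_lesion(1, (30, 36, 30), 10)], np.array([1.0]))

    def test_save_load_roundtrip(self, toy_training, tmp_path):
        images, scores = toy_training
        res = fit_cnn(images, scores, CNNConfig(epochs=1, seed=9))
        res.save(tmp_path / "cnn.npz")
        back = CNNResults.load(tmp_path / "cnn.npz")
        assert np.allclose(back.predict(images[:3]), res.predict(images[:3]), atol=1e-7)


class TestFeatureExtraction:
    def test_feature_vector_length_500_nonnegative_deterministic(self):
        images = [generate_lesion(i, (20, 30, 25), 100 + 60 * i) for i in range(6)]
        scores = np.linspace(-2, 2, 6)
        res = fit_cnn(images, scores, CNNConfig(epochs=1, seed=5))
        F = extract_cnn_features(res, images)
        assert F.shape == (6, 500)
        assert (F >= 0).all()
        F2 = extract_cnn_features(res, images)
        assert (F == F2).all()

    def test_forward_api_and_state_errors(self):
        images = [generate_lesion(i, (20, 30, 25), 80) for i in range(4)]
        res = fit_cnn(images, np.arange(4.0), CNNConfig(epochs=1, seed=2))
        out = cnn_forward(res, images[0])
        assert 0.0 < out < 1.0
        with pytest.raises(StateError):
            cnn_forward("not a model", images[0])
        with pytest.raises(StateError):
            extract_cnn_features(None, images)
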