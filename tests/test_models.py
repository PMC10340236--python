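import math

import numpy as np
import pytest

from gastromut import models as M
from gastromut.errors import ConfigurationError, ValidationError


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


class TestConstruction:
    @pytest.mark.parametrize("arch", M.ARCHITECTURES)
    def test_parameter_count_matches_closed_form(self, arch):
        spec = M.ModelSpec(arch)
        model = M.build_model(spec, 150, seed=0)
        assert model.n_parameters == M.expected_parameter_count(spec)

    def test_scaled_widths_counts(self):
        spec = M.ModelSpec("gru", widths=(16, 8))
        model = M.build_model(spec, 20, seed=0)
        assert model.n_parameters == M.expected_parameter_count(spec)

    def test_same_seed_identical_parameters(self):
        a = M.build_model(M.ModelSpec("lstm", widths=(6,)), 12, seed=5)
        b = M.build_model(M.ModelSpec("lstm", widths=(6,)), 12, seed=5)
        for pa, pb in zip(a.parameters, b.parameters):
            assert np.array_equal(pa, pb)

    def test_unknown_architecture(self):
        with pytest.raises(ConfigurationError):
            M.ModelSpec("transformer")

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(0)
        model = M.build_model(M.ModelSpec("lstm", widths=(5,)), 9, seed=1)
        p = model.predict_proba(rng.normal(scale=5, size=(20, 9)))
        assert np.all((p >= 0) & (p <= 1))


class TestGateAlgebra:
    """One-step cell updates must match hand-computed canonical equations."""

    def test_lstm_single_unit_two_steps(self):
        layer = M.LSTM(1, 1, np.random.default_rng(0))
        # overwrite with fixed scalar weights; column order is [i, f, g, o]
        layer.W[...] = [[0.5, -0.3, 0.8, 0.1]]
        layer.U[...] = [[0.2, 0.4, -0.5, 0.3]]
        layer.b[...] = [0.1, -0.2, 0.05, 0.0]
        x = np.array([[[0.7], [-1.2]]])
        out = layer.forward(x)
        h, c = 0.0, 0.0
        for xt in (0.7, -1.2):
            i = sigmoid(0.5 * xt + 0.2 * h + 0.1)
            f = sigmoid(-0.3 * xt + 0.4 * h - 0.2)
            g = math.tanh(0.8 * xt - 0.5 * h + 0.05)
            o = sigmoid(0.1 * xt + 0.3 * h + 0.0)
            c = f * c + i * g
            h = o * math.tanh(c)
        assert out[0, 0] == pytest.approx(h, abs=1e-6)

    def test_gru_single_unit_two_steps(self):
        layer = M.GRU(1, 1, np.random.default_rng(0))
        # column order is [z (update), r (reset), candidate]
        layer.W[...] = [[0.4, -0.6, 0.9]]
        layer.U[...] = [[0.3, 0.2, -0.7]]
        layer.b[...] = [0.0, 0.1, -0.05]
        x = np.array([[[1.1], [0.4]]])
        out = layer.forward(x)
        h = 0.0
        for xt in (1.1, 0.4):
            z = sigmoid(0.4 * xt + 0.3 * h + 0.0)
            r = sigmoid(-0.6 * xt + 0.2 * h + 0.1)
            cand = math.tanh(0.9 * xt - 0.7 * (r * h) - 0.05)
            h = z * cand + (1.0 - z) * h
        assert out[0, 0] == pytest.approx(h, abs=1e-6)

    def test_bidirectional_mirror_on_palindrome(self):
        rng = np.random.default_rng(3)
        layer = M.Bidirectional(1, 3, rng, return_sequences=True)
        # share weights between directions
        for pf, pb in zip(layer.forward_layer.params, layer.backward_layer.params):
            pb[...] = pf
        x = np.array([0.3, -1.0, 0.5, -1.0, 0.3])[None, :, None]  # palindrome
        out = layer.forward(x)
        fw, bw = out[0, :, :3], out[0, :, 3:]
        assert np.allclose(bw, fw[::-1], atol=1e-12)


class TestBackpropagation:
    @pytest.mark.parametrize(
        "arch,widths", [("lstm", (5,)), ("gru", (4, 3)), ("bilstm", (3, 2))]
    )
    def test_gradients_match_finite_differences(self, arch, widths):
        rng = np.random.default_rng(0)
        spec = M.ModelSpec(arch, dropout_fraction=0.0, widths=widths, dense_units=4)
        model = M.RNNClassifier(spec, input_length=7, seed=1)
        X = rng.normal(size=(6, 7))
        y = np.array([0, 1, 1, 0, 1, 0], dtype=float)

        def loss():
            p = np.clip(model._forward(X, training=False), 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        p = np.clip(model._forward(X, training=False), 1e-12, 1 - 1e-12)
        model._backward((p - y)[:, None] / (p * (1 - p))[:, None] / y.size)
        analytic = [g.copy() for layer in model.layers for g in layer.grads]
        eps = 1e-6
        for pi, param in enumerate(model.parameters):
            flat = param.ravel()
            for k in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                old = flat[k]
                flat[k] = old + eps
                lp = loss()
                flat[k] = old - eps
                lm = loss()
                flat[k] = old
                numeric = (lp - lm) / (2 * eps)
                a = analytic[pi].ravel()[k]
                assert a == pytest.approx(numeric, rel=1e-3, abs=1e-7)


@pytest.fixture(scope="module")
def separable_fixture():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(50, 12))
    y = rng.integers(0, 2, size=50)
    # class-1 rows shifted by a clean margin: linearly separable in the mean
    X[y == 1] += 2.0
    return X, y


class TestTraining:
    def test_learns_separable_data(self, separable_fixture):
        X, y = separable_fixture
        model = M.build_model(M.ModelSpec("lstm", widths=(8,), dense_units=8), 12, seed=0)
        model.fit(X, y, M.TrainingConfig(epochs=60, seed=0))
        _, labels = model.predict(X)
        assert (labels == y).mean() >= 0.95

    def test_history_length_equals_epochs(self, separable_fixture):
        X, y = separable_fixture
        model = M.build_model(M.ModelSpec("lstm", widths=(4,), dense_units=4), 12, seed=0)
        hist = model.fit(X, y, M.TrainingConfig(epochs=1, seed=0))
        assert len(hist["loss"]) == 1 and len(hist["accuracy"]) == 1

    def test_seeded_reproducibility(self, separable_fixture):
        X, y = separable_fixture
        losses = []
        for _ in range(2):
            model = M.build_model(M.ModelSpec("gru", widths=(5, 4), dense_units=4), 12, seed=3)
            hist = model.fit(X, y, M.TrainingConfig(epochs=3, seed=3))
            losses.append(hist["loss"][-1])
        assert losses[0] == losses[1]

    def test_single_class_rejected(self, separable_fixture):
        X, _ = separable_fixture
        model = M.build_model(M.ModelSpec("lstm", widths=(4,)), 12, seed=0)
        with pytest.raises(ConfigurationError):
            model.fit(X, np.ones(len(X)), M.TrainingConfig(epochs=1))

    def test_nan_features_rejected(self, separable_fixture):
        X, y = separable_fixture
        X = X.copy()
        X[0, 0] = np.nan
        model = M.build_model(M.ModelSpec("lstm", widths=(4,)), 12, seed=0)
        with pytest.raises(ValidationError):
            model.fit(X, y, M.TrainingConfig(epochs=1))


class TestPrediction:
    def test_layout_mismatch(self):
        model = M.build_model(M.ModelSpec("lstm", widths=(4,)), 12, seed=0)
        with pytest.raises(ValidationError):
            model.predict(np.zeros((3, 5)))

    def test_empty_input(self):
        model = M.build_model(M.ModelSpec("lstm", widths=(4,)), 12, seed=0)
        probs, labels = model.predict(np.empty((0, 12)))
        assert probs.size == 0 and labels.size == 0

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        model = M.build_model(M.ModelSpec("lstm", widths=(4,)), 10, seed=0)
        X = rng.normal(size=(8, 10))
        p = model.predict_proba(X)
        perm = rng.permutation(8)
        assert np.allclose(model.predict_proba(X[perm]), p[perm], atol=1e-12)

    def test_save_load_round_trip(self, tmp_path, separable_fixture):
        X, y = separable_fixture
        model = M.build_model(M.ModelSpec("lstm", widths=(4,), dense_units=4), 12, seed=0)
        model.fit(X, y, M.TrainingConfig(epochs=2, seed=0))
        model.save(tmp_path / "model.npz")
        loaded = M.RNNClassifier.load(tmp_path / "model.npz")
        assert np.allclose(loaded.predict_proba(X), model.predict_proba(X))
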