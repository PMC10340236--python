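"""Recurrent binary classifiers (LSTM, GRU, Bi-LSTM) in pure numpy.

Each feature vector is treated as a univariate series of length equal to the
feature dimensionality and fed through one of three stacked architectures:

* ``lstm``    — LSTM(128) → dropout → dense(64, relu) → dropout → sigmoid unit
* ``gru``     — GRU(256) → dropout → LSTM(128) → dropout → sigmoid unit
* ``bilstm``  — BiLSTM(512) → dropout → BiLSTM(256) → dropout →
  dense(64, relu) → dropout → sigmoid unit

(dropout fraction 0.2 throughout; recurrent widths are per direction and may
be scaled down for small corpora).

Cells follow the canonical recurrences.  LSTM:

    i = σ(W_i x + U_i h + b_i)      f = σ(W_f x + U_f h + b_f)
    g = tanh(W_g x + U_g h + b_g)   o = σ(W_o x + U_o h + b_o)
    c_t = f ∗ c_{t-1} + i ∗ g       h_t = o ∗ tanh(c_t)

GRU (update gate z, reset gate r):

    c~  = tanh(W_c x + U_c (r ∗ h_{t-1}) + b_c)
    h_t = z ∗ c~ + (1 − z) ∗ h_{t-1}

Training minimises binary cross-entropy with Adam (1e-3, β = 0.9/0.999),
batch size 32; forward, backward-through-time and the optimiser are
implemented here directly so the package has no deep-learning framework
dependency.  All randomness (weight init, shuffling, dropout masks) flows
from explicit seeds, so runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

ARCHITECTURES = ("lstm", "gru", "bilstm")

_DEFAULT_WIDTHS = {"lstm": (128,), "gru": (256, 128), "bilstm": (512, 256)}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture selection; ``widths`` overrides the canonical layer sizes."""

    architecture: str
    dropout_fraction: float = 0.2
    widths: tuple[int, ...] | None = None
    dense_units: int = 64

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ConfigurationError("dropout fraction must be in [0, 1)")

    @property
    def layer_widths(self) -> tuple[int, ...]:
        return self.widths or _DEFAULT_WIDTHS[self.architecture]


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    clip_norm: float = 1.0  # global gradient-norm clipping; 0 disables
    seed: int = 0
    classification_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if not 0.0 < self.classification_threshold < 1.0:
            raise ConfigurationError("classification threshold must lie in (0, 1)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int, cols: int) -> np.ndarray:
    """Block-orthogonal recurrent init (one orthogonal block per gate)."""
    blocks = []
    for _ in range(cols // n):
        a = rng.normal(size=(n, n))
        q, r = np.linalg.qr(a)
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x, *, training=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, input_dim: int, units: int, activation: str, rng: np.random.Generator):
        self.activation = activation
        self.W = _glorot(rng, input_dim, units)
        self.b = np.zeros(units)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        if self.activation == "sigmoid":
            self._a = _sigmoid(z)
            return self._a
        self._z = z
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        elif self.activation == "sigmoid":
            grad = grad * self._a * (1.0 - self._a)
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    def __init__(self, rate: float):
        self.rate = rate
        self.params, self.grads = [], []

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class LSTM(Layer):
    """LSTM over (B, T, D) input; emits (B, T, U) or the last state (B, U)."""

    def __init__(
        self,
        input_dim: int,
        units: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
        go_backwards: bool = False,
    ):
        self.units = units
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        self.W = _glorot(rng, input_dim, 4 * units)
        self.U = _orthogonal(rng, units, 4 * units)
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0  # forget-gate bias
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, *, training=False, rng=None):
        if self.go_backwards:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        zx = x.reshape(B * T, -1) @ self.W  # input contribution, all steps at once
        zx = zx.reshape(B, T, 4 * U) + self.b
        cache = []
        hs = np.empty((B, T, U))
        for t in range(T):
            z = zx[:, t] + h @ self.U
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = _sigmoid(z[:, 3 * U :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, h_prev, tc))
        self._x, self._cache, self._hs = x, cache, hs
        if self.return_sequences:
            return hs[:, ::-1, :] if self.go_backwards else hs
        return h

    def backward(self, grad):
        x, cache = self._x, self._cache
        B, T, D = x.shape
        U = self.units
        if self.return_sequences:
            dhs = grad[:, ::-1, :] if self.go_backwards else grad
        else:
            dhs = None
        dW, dU_, db = (np.zeros_like(p) for p in self.params)
        dx = np.empty((B, T, D))
        dh_carry = np.zeros((B, U)) if dhs is not None else grad.copy()
        dc_carry = np.zeros((B, U))
        for t in reversed(range(T)):
            i, f, g, o, c_prev, h_prev, tc = cache[t]
            # for last-state output the incoming gradient was seeded into
            # dh_carry before the loop and only flows through recurrence
            dh = dh_carry + (dhs[:, t] if dhs is not None else 0.0)
            do = dh * tc
            dc = dc_carry + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += x[:, t].T @ dz
            dU_ += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.W.T
            dh_carry = dz @ self.U.T
            dc_carry = dc * f
        self.grads[0][...] = dW
        self.grads[1][...] = dU_
        self.grads[2][...] = db
        return dx[:, ::-1, :] if self.go_backwards else dx


class GRU(Layer):
    """GRU over (B, T, D); update/reset gates, reset applied before the candidate."""

    def __init__(
        self,
        input_dim: int,
        units: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
    ):
        self.units = units
        self.return_sequences = return_sequences
        self.W = _glorot(rng, input_dim, 3 * units)
        self.U = _orthogonal(rng, units, 3 * units)
        self.b = np.zeros(3 * units)
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, *, training=False, rng=None):
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U))
        zx = (x.reshape(B * T, -1) @ self.W).reshape(B, T, 3 * U) + self.b
        cache = []
        hs = np.empty((B, T, U))
        Uz, Ur, Uc = self.U[:, :U], self.U[:, U : 2 * U], self.U[:, 2 * U :]
        for t in range(T):
            z = _sigmoid(zx[:, t, :U] + h @ Uz)
            r = _sigmoid(zx[:, t, U : 2 * U] + h @ Ur)
            rh = r * h
            cand = np.tanh(zx[:, t, 2 * U :] + rh @ Uc)
            h_prev = h
            h = z * cand + (1.0 - z) * h_prev
            hs[:, t] = h
            cache.append((z, r, cand, h_prev, rh))
        self._x, self._cache = x, cache
        return hs if self.return_sequences else h

    def backward(self, grad):
        x, cache = self._x, self._cache
        B, T, D = x.shape
        U = self.units
        Uz, Ur, Uc = self.U[:, :U], self.U[:, U : 2 * U], self.U[:, 2 * U :]
        dW, dU_, db = (np.zeros_like(p) for p in self.params)
        dx = np.empty((B, T, D))
        dh_carry = np.zeros((B, U)) if self.return_sequences else grad.copy()
        for t in reversed(range(T)):
            z, r, cand, h_prev, rh = cache[t]
            dh = dh_carry + (grad[:, t] if self.return_sequences else 0.0)
            dz_gate = dh * (cand - h_prev)
            dcand = dh * z
            dh_prev = dh * (1.0 - z)
            da = dcand * (1.0 - cand * cand)
            drh = da @ Uc.T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            dz_pre = dz_gate * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            dzrc = np.concatenate([dz_pre, dr_pre, da], axis=1)
            dW += x[:, t].T @ dzrc
            dU_[:, :U] += h_prev.T @ dz_pre
            dU_[:, U : 2 * U] += h_prev.T @ dr_pre
            dU_[:, 2 * U :] += rh.T @ da
            db += dzrc.sum(axis=0)
            dx[:, t] = dzrc @ self.W.T
            dh_carry = dh_prev + dz_pre @ Uz.T + dr_pre @ Ur.T
        self.grads[0][...] = dW
        self.grads[1][...] = dU_
        self.grads[2][...] = db
        return dx


class Bidirectional(Layer):
    """Two LSTMs over opposite directions, outputs concatenated."""

    def __init__(
        self,
        input_dim: int,
        units: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
    ):
        self.forward_layer = LSTM(input_dim, units, rng, return_sequences=return_sequences)
        self.backward_layer = LSTM(
            input_dim, units, rng, return_sequences=return_sequences, go_backwards=True
        )
        self.units = 2 * units
        self.return_sequences = return_sequences
        self.params = self.forward_layer.params + self.backward_layer.params
        self.grads = self.forward_layer.grads + self.backward_layer.grads

    def forward(self, x, *, training=False, rng=None):
        fw = self.forward_layer.forward(x, training=training, rng=rng)
        bw = self.backward_layer.forward(x, training=training, rng=rng)
        return np.concatenate([fw, bw], axis=-1)

    def backward(self, grad):
        u = self.forward_layer.units
        dfw = self.forward_layer.backward(grad[..., :u])
        dbw = self.backward_layer.backward(grad[..., u:])
        return dfw + dbw


class RNNClassifier:
    """A stacked recurrent binary classifier over univariate feature series."""

    def __init__(self, spec: ModelSpec, input_length: int, seed: int = 0):
        if input_length < 1:
            raise ConfigurationError("input_length must be >= 1")
        self.spec = spec
        self.input_length = input_length
        self.seed = seed
        rng = np.random.default_rng(seed)
        d = spec.dropout_fraction
        w = spec.layer_widths
        layers: list[Layer] = []
        if spec.architecture == "lstm":
            layers += [LSTM(1, w[0], rng), Dropout(d)]
            layers += [Dense(w[0], spec.dense_units, "relu", rng), Dropout(d)]
            head_in = spec.dense_units
        elif spec.architecture == "gru":
            layers += [GRU(1, w[0], rng, return_sequences=True), Dropout(d)]
            layers += [LSTM(w[0], w[1], rng), Dropout(d)]
            head_in = w[1]
        else:  # bilstm
            layers += [Bidirectional(1, w[0], rng, return_sequences=True), Dropout(d)]
            layers += [Bidirectional(2 * w[0], w[1], rng), Dropout(d)]
            layers += [Dense(2 * w[1], spec.dense_units, "relu", rng), Dropout(d)]
            head_in = spec.dense_units
        layers.append(Dense(head_in, 1, "sigmoid", rng))
        self.layers = layers
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        self.config: TrainingConfig | None = None

    # -- plumbing ---------------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1 and X.size == 0:
            X = X.reshape(0, self.input_length)
        if X.ndim != 2 or (X.size and X.shape[1] != self.input_length):
            raise ValidationError(
                f"feature layout mismatch: expected {self.input_length} columns, "
                f"got shape {X.shape}"
            )
        if np.isnan(X).any() or np.isinf(X).any():
            raise ValidationError("feature matrix contains NaN or infinite values")
        return X

    def _forward(self, X: np.ndarray, training: bool, rng=None) -> np.ndarray:
        out = X[:, :, None]  # univariate series (B, T, 1)
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out[:, 0]

    # -- API --------------------------------------------------------------
    def fit(self, X: np.ndarray, y: Sequence[int], cfg: TrainingConfig) -> dict:
        X = self._check_X(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.size or X.shape[0] < 2:
            raise ValidationError("need at least two samples with matching labels")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ConfigurationError(
                f"training labels must contain both classes, got {classes.tolist()}"
            )
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        opt_m = [np.zeros_like(p) for p in self.parameters]
        opt_v = [np.zeros_like(p) for p in self.parameters]
        step = 0
        n = X.shape[0]
        self.history = {"loss": [], "accuracy": []}
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses, hits, seen = 0.0, 0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                p = self._forward(xb, training=True, rng=rng)
                pc = np.clip(p, 1e-12, 1.0 - 1e-12)
                losses += float(-np.sum(yb * np.log(pc) + (1 - yb) * np.log(1 - pc)))
                hits += int(np.sum((p >= cfg.classification_threshold) == yb))
                seen += idx.size
                # combined sigmoid+BCE gradient w.r.t. the head pre-activation
                # is (p - y); push (p - y)/B through the sigmoid-inverse trick:
                grad = (pc - yb)[:, None] / (pc * (1.0 - pc))[:, None] / idx.size
                self._backward(grad)
                grads = [g for l in self.layers for g in l.grads]
                if cfg.clip_norm > 0:
                    gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                    if gnorm > cfg.clip_norm:
                        scale = cfg.clip_norm / gnorm
                        for g in grads:
                            g *= scale
                step += 1
                lr_t = (
                    cfg.learning_rate
                    * np.sqrt(1.0 - cfg.beta2**step)
                    / (1.0 - cfg.beta1**step)
                )
                for pi, (param, g) in enumerate(zip(self.parameters, grads)):
                    opt_m[pi] = cfg.beta1 * opt_m[pi] + (1 - cfg.beta1) * g
                    opt_v[pi] = cfg.beta2 * opt_v[pi] + (1 - cfg.beta2) * g * g
                    param -= lr_t * opt_m[pi] / (np.sqrt(opt_v[pi]) + cfg.epsilon)
            self.history["loss"].append(losses / seen)
            self.history["accuracy"].append(hits / seen)
        return self.history

    def _backward(self, grad: np.ndarray) -> None:
        out = grad
        for layer in reversed(self.layers):
            out = layer.backward(out)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        if X.shape[0] == 0:
            return np.empty(0)
        return self._forward(X, training=False)

    def predict(self, X: np.ndarray, threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        thr = threshold if threshold is not None else (
            self.config.classification_threshold if self.config else 0.5
        )
        p = self.predict_proba(X)
        return p, (p >= thr).astype(int)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **{f"p{i}": p for i, p in enumerate(self.parameters)})
        meta = {
            "architecture": self.spec.architecture,
            "dropout_fraction": self.spec.dropout_fraction,
            "widths": list(self.spec.layer_widths),
            "dense_units": self.spec.dense_units,
            "input_length": self.input_length,
            "seed": self.seed,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "RNNClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = ModelSpec(
            architecture=meta["architecture"],
            dropout_fraction=meta["dropout_fraction"],
            widths=tuple(meta["widths"]),
            dense_units=meta["dense_units"],
        )
        model = cls(spec, meta["input_length"], seed=meta["seed"])
        data = np.load(str(path) if str(path).endswith(".npz") else f"{path}.npz")
        for i, p in enumerate(model.parameters):
            p[...] = data[f"p{i}"]
        model.history = meta["history"]
        return model


def expected_parameter_count(spec: ModelSpec, input_dim: int = 1) -> int:
    """Closed-form parameter count for the stated layer plan.

    LSTM: 4U(D + U + 1); GRU: 3U(D + U + 1); bidirectional doubles an LSTM;
    dense: U(D + 1).
    """
    w = spec.layer_widths
    d = spec.dense_units

    def lstm(D, U):
        return 4 * U * (D + U + 1)

    def gru(D, U):
        return 3 * U * (D + U + 1)

    def dense(D, U):
        return U * (D + 1)

    if spec.architecture == "lstm":
        return lstm(input_dim, w[0]) + dense(w[0], d) + dense(d, 1)
    if spec.architecture == "gru":
        return gru(input_dim, w[0]) + lstm(w[0], w[1]) + dense(w[1], 1)
    return (
        2 * lstm(input_dim, w[0])
        + 2 * lstm(2 * w[0], w[1])
        + dense(2 * w[1], d)
        + dense(d, 1)
    )


# -- module-level operation wrappers --------------------------------------

def build_model(spec: ModelSpec, input_length: int, seed: int = 0) -> RNNClassifier:
    """Construct an untrained classifier for feature vectors of ``input_length``."""
    return RNNClassifier(spec, input_length, seed=seed)


def train(model: RNNClassifier, X, y, cfg: TrainingConfig) -> RNNClassifier:
    model.fit(X, y, cfg)
    return model


def predict(model: RNNClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(X)
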