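"""Recurrent sequence classifiers with a closed-form parameter counter.

A self-contained numpy engine implementing the three architectures the
tuning stage searches over:

* ``lstm``  — LayerNorm (optional) -> LSTM(n1, sequences) -> LSTM(n2, last) -> softmax
* ``gru``   — same stack with double-bias ("reset-after") GRU cells
* ``bidirectional`` — stacked bidirectional LSTM layers (outputs of the
  forward and backward passes concatenated)

Cell-state/candidate activations use SELU (gates stay sigmoid), the
head is a dense softmax over the five movement classes, training uses
Adam with categorical cross-entropy and patience-based early stopping
on validation accuracy. All gradients are hand-derived backprop,
verified against central finite differences in the test suite.

Windows enter as sequences of ``input_timesteps`` x ``input_features``;
by default the four channels are the sequence axis (4 steps of 375
samples each).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772

ARCHITECTURES = ("lstm", "gru", "bidirectional")


def selu(x):
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0))


def selu_grad(x):
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class ModelSpec:
    """Architecture + optimizer settings for one candidate classifier."""

    arch: str = "lstm"
    n1: int = 28
    n2: int = 74
    input_timesteps: int = 4
    input_features: int = 375
    n_classes: int = 5
    activation: str = "selu"
    normalize_input: bool = True
    lr: float = 1e-3

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown arch {self.arch!r}; choose from {ARCHITECTURES}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.activation != "selu":
            raise ValueError("only the selu activation is supported")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    max_epochs: int = 10
    patience: int = 5
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch_size, max_epochs and patience must be >= 1")


@dataclass
class TrainingResult:
    final_train_accuracy: float
    final_val_accuracy: float
    best_val_accuracy: float
    effective_epochs: int
    history: dict


# ---------------------------------------------------------------------------
# Closed-form trainable-parameter counting


def lstm_param_count(n_inputs: int, units: int) -> int:
    """4 gates, each units x (inputs + units) weights + units biases."""
    return 4 * (units * (n_inputs + units) + units)


def gru_param_count(n_inputs: int, units: int) -> int:
    """Double-bias (reset-after) convention: separate input and
    recurrent bias per gate -> 3*(f*u + u^2 + 2u)."""
    return 3 * (n_inputs * units + units * units + 2 * units)


def count_trainable_params(spec: ModelSpec) -> int:
    """Closed-form count for the stacked architecture of ``spec``."""
    total = 0
    f = spec.input_features
    if spec.normalize_input:
        total += 2 * f  # gamma + beta over the feature axis
    if spec.arch == "lstm":
        total += lstm_param_count(f, spec.n1)
        total += lstm_param_count(spec.n1, spec.n2)
        head_in = spec.n2
    elif spec.arch == "gru":
        total += gru_param_count(f, spec.n1)
        total += gru_param_count(spec.n1, spec.n2)
        head_in = spec.n2
    else:  # bidirectional LSTM: each layer doubled; downstream width doubled
        total += 2 * lstm_param_count(f, spec.n1)
        total += 2 * lstm_param_count(2 * spec.n1, spec.n2)
        head_in = 2 * spec.n2
    total += (head_in + 1) * spec.n_classes
    return total


# ---------------------------------------------------------------------------
# Layers (forward + manual backprop)


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng, n):
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class LayerNorm:
    """Trainable per-feature normalization applied at every timestep."""

    def __init__(self, features, rng=None, eps=1e-3):
        self.gamma = np.ones(features)
        self.beta = np.zeros(features)
        self.eps = eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x):
        # x: (B, T, F); normalize over F
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        self._cache = (xhat, inv)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv = self._cache
        F = xhat.shape[-1]
        grads = {
            "gamma": np.sum(dout * xhat, axis=(0, 1)),
            "beta": np.sum(dout, axis=(0, 1)),
        }
        dxhat = dout * self.gamma
        dx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        return dx, grads


class LSTMLayer:
    """Standard 4-gate LSTM; candidate/state activation is SELU."""

    def __init__(self, n_inputs, units, return_sequences, rng, reverse=False):
        self.n_inputs, self.units = n_inputs, units
        self.return_sequences = return_sequences
        self.reverse = reverse
        u = units
        self.W = _glorot(rng, (n_inputs, 4 * u))
        self.U = np.concatenate([_orthogonal(rng, u) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * u)
        self.b[u : 2 * u] = 1.0  # unit forget-gate bias

    def params(self):
        return {"W": self.W, "U": self.U, "b": self.b}

    def forward(self, x):
        if self.reverse:
            x = x[:, ::-1, :]
        B, T, _ = x.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        hs = np.empty((B, T, u))
        cache = []
        for t in range(T):
            z = x[:, t, :] @ self.W + h @ self.U + self.b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u : 2 * u])
            g = selu(z[:, 2 * u : 3 * u])
            o = sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = selu(c_new)
            h_new = o * tc
            cache.append((x[:, t, :], h, c, i, f, g, o, z[:, 2 * u : 3 * u], c_new, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = (cache, x.shape)
        if self.return_sequences:
            return hs[:, ::-1, :] if self.reverse else hs
        return h

    def backward(self, dout):
        cache, (B, T, F) = self._cache
        u = self.units
        if self.return_sequences and self.reverse:
            dout = dout[:, ::-1, :]
        grads = {"W": np.zeros_like(self.W), "U": np.zeros_like(self.U), "b": np.zeros_like(self.b)}
        dx = np.empty((B, T, F))
        dh_next = np.zeros((B, u))
        dc_next = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, zg, c_new, tc = cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dout[:, t, :]
            elif t == T - 1:
                dh += dout
            do = dh * tc
            dc = dc_next + dh * o * selu_grad(c_new)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * selu_grad(zg), do * o * (1 - o)],
                axis=1,
            )
            grads["W"] += x_t.T @ dz
            grads["U"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        if self.reverse:
            dx = dx[:, ::-1, :]
        return dx, grads


class GRULayer:
    """Double-bias (reset-after) GRU; candidate activation is SELU."""

    def __init__(self, n_inputs, units, return_sequences, rng):
        self.n_inputs, self.units = n_inputs, units
        self.return_sequences = return_sequences
        u = units
        self.W = _glorot(rng, (n_inputs, 3 * u))
        self.U = np.concatenate([_orthogonal(rng, u) for _ in range(3)], axis=1)
        self.b_in = np.zeros(3 * u)
        self.b_rec = np.zeros(3 * u)

    def params(self):
        return {"W": self.W, "U": self.U, "b_in": self.b_in, "b_rec": self.b_rec}

    def forward(self, x):
        B, T, _ = x.shape
        u = self.units
        h = np.zeros((B, u))
        hs = np.empty((B, T, u))
        cache = []
        for t in range(T):
            xw = x[:, t, :] @ self.W + self.b_in
            hu = h @ self.U + self.b_rec
            z = sigmoid(xw[:, :u] + hu[:, :u])
            r = sigmoid(xw[:, u : 2 * u] + hu[:, u : 2 * u])
            a_h = xw[:, 2 * u :] + r * hu[:, 2 * u :]
            cand = selu(a_h)
            h_new = z * h + (1 - z) * cand
            cache.append((x[:, t, :], h, z, r, a_h, cand, hu[:, 2 * u :]))
            h = h_new
            hs[:, t, :] = h
        self._cache = (cache, x.shape)
        return hs if self.return_sequences else h

    def backward(self, dout):
        cache, (B, T, F) = self._cache
        u = self.units
        grads = {
            "W": np.zeros_like(self.W),
            "U": np.zeros_like(self.U),
            "b_in": np.zeros_like(self.b_in),
            "b_rec": np.zeros_like(self.b_rec),
        }
        dx = np.empty((B, T, F))
        dh_next = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, z, r, a_h, cand, hh = cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dout[:, t, :]
            elif t == T - 1:
                dh += dout
            dz = dh * (h_prev - cand)
            dcand = dh * (1 - z)
            da_h = dcand * selu_grad(a_h)
            dr = da_h * hh
            dzpre = dz * z * (1 - z)
            drpre = dr * r * (1 - r)
            dxw = np.concatenate([dzpre, drpre, da_h], axis=1)
            dhu = np.concatenate([dzpre, drpre, da_h * r], axis=1)
            grads["W"] += x_t.T @ dxw
            grads["U"] += h_prev.T @ dhu
            grads["b_in"] += dxw.sum(axis=0)
            grads["b_rec"] += dhu.sum(axis=0)
            dx[:, t, :] = dxw @ self.W.T
            dh_next = dhu @ self.U.T + dh * z
        return dx, grads


class Bidirectional:
    """Wraps a forward and a backward LSTM; outputs concatenated."""

    def __init__(self, n_inputs, units, return_sequences, rng):
        self.fwd = LSTMLayer(n_inputs, units, return_sequences, rng, reverse=False)
        self.bwd = LSTMLayer(n_inputs, units, return_sequences, rng, reverse=True)
        self.units = 2 * units
        self.return_sequences = return_sequences

    def params(self):
        out = {}
        for tag, layer in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in layer.params().items():
                out[f"{tag}_{k}"] = v
        return out

    def forward(self, x):
        yf = self.fwd.forward(x)
        yb = self.bwd.forward(x)
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dout):
        u = self.units // 2
        if self.return_sequences:
            df, db = dout[..., :u], dout[..., u:]
        else:
            df, db = dout[:, :u], dout[:, u:]
        dxf, gf = self.fwd.backward(df)
        dxb, gb = self.bwd.backward(db)
        grads = {f"fwd_{k}": v for k, v in gf.items()}
        grads.update({f"bwd_{k}": v for k, v in gb.items()})
        return dxf + dxb, grads

    def set_param(self, name, value):
        tag, key = name.split("_", 1)
        setattr(self.fwd if tag == "fwd" else self.bwd, key, value)


class Dense:
    def __init__(self, n_inputs, n_outputs, rng):
        self.W = _glorot(rng, (n_inputs, n_outputs))
        self.b = np.zeros(n_outputs)

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.W.T, grads


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Model


class SequenceClassifier:
    """The stacked recurrent classifier; see :func:`build_model`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
        self.layers = []
        f = spec.input_features
        if spec.normalize_input:
            self.layers.append(LayerNorm(f))
        if spec.arch == "lstm":
            self.layers.append(LSTMLayer(f, spec.n1, True, rng))
            self.layers.append(LSTMLayer(spec.n1, spec.n2, False, rng))
            head_in = spec.n2
        elif spec.arch == "gru":
            self.layers.append(GRULayer(f, spec.n1, True, rng))
            self.layers.append(GRULayer(spec.n1, spec.n2, False, rng))
            head_in = spec.n2
        else:
            self.layers.append(Bidirectional(f, spec.n1, True, rng))
            self.layers.append(Bidirectional(2 * spec.n1, spec.n2, False, rng))
            head_in = 2 * spec.n2
        self.layers.append(Dense(head_in, spec.n_classes, rng))

    # -- parameter plumbing -------------------------------------------------
    def named_params(self):
        for li, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                yield f"layer{li}.{name}", arr

    def n_params(self) -> int:
        """Introspected count: total elements actually allocated."""
        return sum(arr.size for _, arr in self.named_params())

    def get_param(self, full_name):
        li, name = full_name.split(".", 1)
        return self.layers[int(li[5:])].params()[name]

    def set_param(self, full_name, value):
        li, name = full_name.split(".", 1)
        layer = self.layers[int(li[5:])]
        if isinstance(layer, Bidirectional):
            layer.set_param(name, value)
        else:
            setattr(layer, name, value)

    def state_dict(self):
        return {k: v.copy() for k, v in self.named_params()}

    def load_state_dict(self, state):
        for k, v in state.items():
            self.set_param(k, v.copy())

    # -- forward / backward -------------------------------------------------
    def _check_layout(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None, ...]
        if x.ndim != 3 or x.shape[1:] != (self.spec.input_timesteps, self.spec.input_features):
            raise ValueError(
                f"expected windows of shape (n, {self.spec.input_timesteps}, "
                f"{self.spec.input_features}), got {np.asarray(x).shape}"
            )
        return x

    def forward(self, x):
        h = self._check_layout(x)
        for layer in self.layers:
            h = layer.forward(h)
        return softmax(h)

    def predict_proba(self, x):
        return self.forward(x)

    def loss_and_grads(self, x, y_onehot):
        probs = self.forward(x)
        n = len(probs)
        loss = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))
        dlogits = (probs - y_onehot) / n
        grads = {}
        d = dlogits
        for li in range(len(self.layers) - 1, -1, -1):
            d, g = self.layers[li].backward(d)
            for name, arr in g.items():
                grads[f"layer{li}.{name}"] = arr
        return loss, grads, probs


def build_model(spec: ModelSpec, seed: int = 0) -> SequenceClassifier:
    """Construct the classifier with seeded weight initialization."""
    return SequenceClassifier(spec, seed=seed)


def predict(model: SequenceClassifier, windows) -> np.ndarray:
    """Class ids in 1..n_classes; argmax ties go to the lowest class."""
    probs = model.predict_proba(windows)
    return np.argmax(probs, axis=1) + 1


def windows_to_sequences(data: np.ndarray, layout: str = "channels_as_steps") -> np.ndarray:
    """Map a (windows, channels, samples) tensor to the model's
    (windows, timesteps, features) layout."""
    if layout == "channels_as_steps":
        return np.asarray(data)
    if layout == "samples_as_steps":
        return np.transpose(np.asarray(data), (0, 2, 1))
    raise ValueError(f"unknown layout {layout!r}")


def one_hot(labels, n_classes) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim == 2:  # already one-hot
        return labels.astype(float)
    if labels.min() < 1 or labels.max() > n_classes:
        raise ValueError(f"labels must lie in 1..{n_classes}")
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels - 1] = 1.0
    return out


class Adam:
    def __init__(self, model, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in model.named_params()}
        self.v = {k: np.zeros_like(v) for k, v in model.named_params()}
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            update = self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            self.model.set_param(k, self.model.get_param(k) - update)


def evaluate_accuracy(model, x, labels, batch_size: int = 4096) -> float:
    correct = 0
    for s in range(0, len(x), batch_size):
        correct += int(np.sum(predict(model, x[s : s + batch_size]) == labels[s : s + batch_size]))
    return correct / len(x)


def train(
    model: SequenceClassifier,
    spec: ModelSpec,
    train_data,
    val_data,
    cfg: TrainConfig,
) -> TrainingResult:
    """Train with Adam + early stopping on validation accuracy.

    ``train_data``/``val_data`` are (windows, labels) with labels in
    1..n_classes (or one-hot rows). Stops once validation accuracy has
    not improved for ``cfg.patience`` consecutive epochs and restores
    the best-validation weights.
    """
    x_train, y_train = train_data
    x_val, y_val = val_data
    x_train = model._check_layout(x_train)
    x_val = model._check_layout(x_val)
    if len(x_train) == 0:
        raise ValueError("empty training set")
    y_hot = one_hot(y_train, spec.n_classes)
    y_train_ids = np.argmax(y_hot, axis=1) + 1
    y_val_ids = (
        np.argmax(y_val, axis=1) + 1 if np.asarray(y_val).ndim == 2 else np.asarray(y_val)
    )

    opt = Adam(model, spec.lr)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "train_accuracy": [], "val_accuracy": []}
    best_val, best_state, since_best = -np.inf, None, 0
    effective_epochs = 0

    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train)) if cfg.shuffle else np.arange(len(x_train))
        losses, correct = [], 0
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            loss, grads, probs = model.loss_and_grads(x_train[idx], y_hot[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch + 1} (lr={spec.lr})"
                )
            correct += int(np.sum(np.argmax(probs, axis=1) + 1 == y_train_ids[idx]))
            losses.append(loss * len(idx))
            opt.step(grads)
        effective_epochs += 1
        train_acc = correct / len(order)
        val_acc = evaluate_accuracy(model, x_val, y_val_ids)
        history["train_loss"].append(float(np.sum(losses) / len(order)))
        history["train_accuracy"].append(train_acc)
        history["val_accuracy"].append(val_acc)
        if val_acc > best_val:
            best_val = val_acc
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                logger.info("early stop at epoch %d (best val %.4f)", effective_epochs, best_val)
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainingResult(
        final_train_accuracy=history["train_accuracy"][-1],
        final_val_accuracy=history["val_accuracy"][-1],
        best_val_accuracy=float(best_val),
        effective_epochs=effective_epochs,
        history=history,
    )


def summary(spec: ModelSpec) -> str:
    """Plain-text block list of the architecture with parameter counts."""
    lines = [f"Model: {spec.arch}  (input {spec.input_timesteps} x {spec.input_features})"]
    f = spec.input_features
    if spec.normalize_input:
        lines.append(f"  LayerNormalization               params={2 * f}")
    if spec.arch == "lstm":
        lines.append(f"  LSTM({spec.n1}, sequences, selu)      params={lstm_param_count(f, spec.n1)}")
        lines.append(f"  LSTM({spec.n2}, last, selu)           params={lstm_param_count(spec.n1, spec.n2)}")
        head_in = spec.n2
    elif spec.arch == "gru":
        lines.append(f"  GRU({spec.n1}, sequences, selu)       params={gru_param_count(f, spec.n1)}")
        lines.append(f"  GRU({spec.n2}, last, selu)            params={gru_param_count(spec.n1, spec.n2)}")
        head_in = spec.n2
    else:
        lines.append(f"  BiLSTM({spec.n1}, sequences, selu)    params={2 * lstm_param_count(f, spec.n1)}")
        lines.append(f"  BiLSTM({spec.n2}, last, selu)         params={2 * lstm_param_count(2 * spec.n1, spec.n2)}")
        head_in = 2 * spec.n2
    lines.append(f"  Dense({spec.n_classes}, softmax)              params={(head_in + 1) * spec.n_classes}")
    lines.append(f"Total trainable parameters: {count_trainable_params(spec)}")
    return "\n".join(lines)
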