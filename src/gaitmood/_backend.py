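"""Minimal NumPy neural-network backend.

Implements exactly what the gait classifier needs: a batched LSTM layer with
full backpropagation through time, dense layers, batch normalization,
inverted dropout, softmax + categorical cross-entropy, and RMSprop with
momentum.  Everything is deterministic given the seeds supplied by the
caller; there is no hidden global state.

Fused LSTM weight layout: ``Wx (D, 4U)``, ``Wh (U, 4U)``, ``b (4U,)`` with
gate blocks ordered [input, forget, candidate, output].  The standard cell
is used: sigmoid input/forget/output gates, tanh candidate and output
squashing, biases on every gate (forget bias initialized to 1).
"""

from __future__ import annotations

import numpy as np

from .errors import ContractError


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: named parameter dict + gradient dict of matching shapes."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.aux: dict[str, np.ndarray] = {}  # non-trainable state (BN stats)

    @property
    def n_trainable(self) -> int:
        return sum(p.size for p in self.params.values())

    @property
    def n_aux(self) -> int:
        return sum(p.size for p in self.aux.values())

    def zero_grads(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class LSTMLayer(Layer):
    """Batched LSTM over (N, T, D) input; returns (N, T, U) sequences or the
    final-step activation (N, U)."""

    def __init__(self, input_dim: int, units: int, return_sequences: bool,
                 rng: np.random.Generator, dtype=np.float64) -> None:
        super().__init__()
        self.input_dim = input_dim
        self.units = units
        self.return_sequences = return_sequences
        u = units
        b = np.zeros(4 * u, dtype=dtype)
        b[u:2 * u] = 1.0  # forget-gate bias
        self.params = {
            "Wx": glorot_uniform(rng, (input_dim, 4 * u), dtype),
            "Wh": glorot_uniform(rng, (u, 4 * u), dtype),
            "b": b,
        }
        self._cache: dict | None = None

    def forward(self, x, training, rng=None):
        if x.ndim != 3 or x.shape[2] != self.input_dim:
            raise ContractError(
                f"LSTM expects (N, T, {self.input_dim}), got {x.shape}"
            )
        n, t, _ = x.shape
        u = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((n, u), dtype=x.dtype)
        c = np.zeros((n, u), dtype=x.dtype)
        # precompute the input projection for all timesteps at once
        zx = x.reshape(n * t, -1) @ Wx
        zx = zx.reshape(n, t, 4 * u)
        hs = np.empty((t, n, u), dtype=x.dtype)
        gates = np.empty((t, n, 4 * u), dtype=x.dtype)  # i, f, g, o post-activation
        cs = np.empty((t, n, u), dtype=x.dtype)
        tanh_cs = np.empty((t, n, u), dtype=x.dtype)
        for k in range(t):
            z = zx[:, k, :] + h @ Wh + b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = sigmoid(z[:, 3 * u:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[k, :, :u] = i
            gates[k, :, u:2 * u] = f
            gates[k, :, 2 * u:3 * u] = g
            gates[k, :, 3 * u:] = o
            cs[k] = c
            tanh_cs[k] = tc
            hs[k] = h
        if training:
            self._cache = {"x": x, "gates": gates, "cs": cs,
                           "tanh_cs": tanh_cs, "hs": hs}
        return hs.transpose(1, 0, 2) if self.return_sequences else h

    def backward(self, dout):
        cache = self._cache
        if cache is None:
            raise ContractError("backward before forward(training=True)")
        x, gates, cs, tanh_cs, hs = (
            cache["x"], cache["gates"], cache["cs"], cache["tanh_cs"], cache["hs"]
        )
        n, t, d = x.shape
        u = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((n, u), dtype=x.dtype)
        dc_next = np.zeros((n, u), dtype=x.dtype)
        if self.return_sequences:
            dout_seq = dout.transpose(1, 0, 2)
        for k in range(t - 1, -1, -1):
            if self.return_sequences:
                dh = dout_seq[k] + dh_next
            else:
                dh = (dout + dh_next) if k == t - 1 else dh_next
            i = gates[k, :, :u]
            f = gates[k, :, u:2 * u]
            g = gates[k, :, 2 * u:3 * u]
            o = gates[k, :, 3 * u:]
            tc = tanh_cs[k]
            c_prev = cs[k - 1] if k > 0 else np.zeros((n, u), dtype=x.dtype)
            h_prev = hs[k - 1] if k > 0 else np.zeros((n, u), dtype=x.dtype)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            dWx += x[:, k, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, k, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        self._cache = None
        return dx


class DenseLayer(Layer):
    def __init__(self, input_dim: int, units: int, activation: str | None,
                 rng: np.random.Generator, dtype=np.float64,
                 zero_init: bool = False) -> None:
        super().__init__()
        if activation not in (None, "tanh"):
            raise ContractError(f"unsupported dense activation {activation!r}")
        self.input_dim = input_dim
        self.units = units
        self.activation = activation
        if zero_init:
            w = np.zeros((input_dim, units), dtype=dtype)
        else:
            w = glorot_uniform(rng, (input_dim, units), dtype)
        self.params = {"W": w, "b": np.zeros(units, dtype=dtype)}
        self._cache = None

    def forward(self, x, training, rng=None):
        if x.ndim != 2 or x.shape[1] != self.input_dim:
            raise ContractError(
                f"Dense expects (N, {self.input_dim}), got {x.shape}"
            )
        z = x @ self.params["W"] + self.params["b"]
        out = np.tanh(z) if self.activation == "tanh" else z
        if training:
            self._cache = (x, out)
        return out

    def backward(self, dout):
        x, out = self._cache
        dz = dout * (1.0 - out * out) if self.activation == "tanh" else dout
        self.grads = {"W": x.T @ dz, "b": dz.sum(axis=0)}
        self._cache = None
        return dz @ self.params["W"].T


class BatchNormLayer(Layer):
    """Batch normalization over the batch axis with running statistics.

    ``momentum`` is the fraction of the batch statistic blended into the
    running statistic each step: running <- (1 - m) * running + m * batch.
    """

    def __init__(self, units: int, momentum: float = 0.1, eps: float = 1e-3,
                 dtype=np.float64) -> None:
        super().__init__()
        self.units = units
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(units, dtype=dtype),
            "beta": np.zeros(units, dtype=dtype),
        }
        self.aux = {
            "running_mean": np.zeros(units, dtype=dtype),
            "running_var": np.ones(units, dtype=dtype),
        }
        self._cache = None

    def forward(self, x, training, rng=None):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.aux["running_mean"] = (
                (1 - self.momentum) * self.aux["running_mean"] + self.momentum * mean
            ).astype(x.dtype)
            self.aux["running_var"] = (
                (1 - self.momentum) * self.aux["running_var"] + self.momentum * var
            ).astype(x.dtype)
        else:
            mean = self.aux["running_mean"]
            var = self.aux["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        out = self.params["gamma"] * xhat + self.params["beta"]
        if training:
            self._cache = (xhat, inv_std)
        return out

    def backward(self, dout):
        xhat, inv_std = self._cache
        n = dout.shape[0]
        gamma = self.params["gamma"]
        self.grads = {
            "gamma": (dout * xhat).sum(axis=0),
            "beta": dout.sum(axis=0),
        }
        dxhat = dout * gamma
        dx = (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        self._cache = None
        return dx


class DropoutLayer(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ContractError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            return x
        if rng is None:
            raise ContractError("dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        self._mask = self._mask.astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


class SequentialModel:
    """Layer stack ending in a linear (logit) dense layer; softmax applied
    by :meth:`predict_proba` / fused into the cross-entropy gradient."""

    def __init__(self, layers: list[Layer], input_dim: int, n_classes: int) -> None:
        self.layers = layers
        self.input_dim = input_dim
        self.n_classes = n_classes

    @property
    def n_trainable(self) -> int:
        return sum(l.n_trainable for l in self.layers)

    @property
    def n_aux(self) -> int:
        return sum(l.n_aux for l in self.layers)

    @property
    def n_parameters(self) -> int:
        """Trainable + auxiliary, matching the closed-form counter."""
        return self.n_trainable + self.n_aux

    def logits(self, x: np.ndarray, training: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x, training=False))

    def loss_and_grad(self, x: np.ndarray, y_onehot: np.ndarray,
                      rng: np.random.Generator) -> tuple[float, np.ndarray]:
        """Mean categorical cross-entropy and parameter gradients (stored on
        each layer); returns (loss, probabilities)."""
        n = x.shape[0]
        z = self.logits(x, training=True, rng=rng)
        probs = softmax(z)
        clipped = np.clip(probs[y_onehot.astype(bool)], 1e-12, 1.0)
        loss = float(-np.log(clipped).mean())
        dlogits = (probs - y_onehot) / n
        grad = dlogits.astype(x.dtype)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss, probs

    # -- persistence -------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                state[f"layer{i:02d}.{k}"] = p
            for k, p in layer.aux.items():
                state[f"layer{i:02d}.aux.{k}"] = p
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                key = f"layer{i:02d}.{k}"
                if key not in state or state[key].shape != p.shape:
                    raise ContractError(f"state mismatch for {key}")
                layer.params[k] = np.asarray(state[key], dtype=p.dtype)
            for k, p in layer.aux.items():
                key = f"layer{i:02d}.aux.{k}"
                if key not in state or state[key].shape != p.shape:
                    raise ContractError(f"state mismatch for {key}")
                layer.aux[k] = np.asarray(state[key], dtype=p.dtype)


class RMSprop:
    """RMSprop with momentum: acc <- rho*acc + (1-rho)*g^2;
    mom <- momentum*mom + lr*g/(sqrt(acc)+eps); w <- w - mom."""

    def __init__(self, learning_rate: float = 1e-4, rho: float = 0.3,
                 momentum: float = 0.5, epsilon: float = 1e-7) -> None:
        self.lr = learning_rate
        self.rho = rho
        self.momentum = momentum
        self.eps = epsilon
        self._acc: dict[int, dict[str, np.ndarray]] = {}
        self._mom: dict[int, dict[str, np.ndarray]] = {}

    def step(self, model: SequentialModel) -> None:
        for i, layer in enumerate(model.layers):
            if not layer.params:
                continue
            acc = self._acc.setdefault(
                i, {k: np.zeros_like(p) for k, p in layer.params.items()}
            )
            mom = self._mom.setdefault(
                i, {k: np.zeros_like(p) for k, p in layer.params.items()}
            )
            for k, p in layer.params.items():
                g = layer.grads[k]
                acc[k] = self.rho * acc[k] + (1.0 - self.rho) * g * g
                mom[k] = self.momentum * mom[k] + self.lr * g / (np.sqrt(acc[k]) + self.eps)
                layer.params[k] = p - mom[k]
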