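"""Bi-modular gait classifier: tapered LSTM sub-network feeding a tapered
MLP sub-network with a softmax output.

This module owns three things:

1. a *reference* recurrent cell (:func:`lstm_cell_step`,
   :func:`lstm_layer_forward`) written gate-by-gate with separate per-gate
   weight matrices — the independent oracle the vectorized training backend
   is checked against;
2. the declarative network builder (:func:`build_network`) producing a
   :class:`ModelSpec`, and :func:`build_model` producing a runnable model on
   the NumPy backend;
3. the closed-form parameter counter (:func:`count_parameters`) — each LSTM
   layer with fan-in d and u units contributes 4*(u*d + u^2 + u), each dense
   layer d -> u contributes d*u + u, and batch normalization on u units
   contributes 4*u (scale, shift and the two running statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _backend
from .errors import ConfigError, ContractError
from .geometric_features import FeatureMatrix


@dataclass(frozen=True)
class NetworkConfig:
    input_dim: int
    sequence_length: int = 240
    lstm_units: tuple[int, ...] = (128, 64, 64)
    mlp_units: tuple[int, ...] = (64, 32, 32)
    n_classes: int = 4
    activation: str = "tanh"
    batchnorm_after_first_mlp: bool = False
    batchnorm_momentum: float = 0.1
    dropout_position: int = 2  # 1-based index of the MLP layer whose output is dropped
    dropout_rate: float = 0.2
    allow_non_tapered: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "lstm_units", tuple(self.lstm_units))
        object.__setattr__(self, "mlp_units", tuple(self.mlp_units))
        if self.input_dim < 1:
            raise ConfigError(f"input_dim must be >= 1, got {self.input_dim}")
        if self.sequence_length < 1:
            raise ConfigError("sequence_length must be >= 1")
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.activation != "tanh":
            raise ConfigError(f"only tanh hidden activation is supported, got {self.activation!r}")
        if not self.lstm_units or not self.mlp_units:
            raise ConfigError("lstm_units and mlp_units must be non-empty")
        if not self.allow_non_tapered:
            for name, units in (("lstm_units", self.lstm_units),
                                ("mlp_units", self.mlp_units)):
                for a, b in zip(units, units[1:]):
                    if b > a:
                        raise ConfigError(
                            f"{name} {units} violates the tapered design "
                            "(each layer must have <= units of the previous); "
                            "pass allow_non_tapered=True to override"
                        )
        if not 1 <= self.dropout_position <= len(self.mlp_units):
            raise ConfigError(
                f"dropout_position {self.dropout_position} outside MLP depth "
                f"{len(self.mlp_units)}"
            )

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "sequence_length": self.sequence_length,
            "lstm_units": list(self.lstm_units),
            "mlp_units": list(self.mlp_units),
            "n_classes": self.n_classes,
            "activation": self.activation,
            "batchnorm_after_first_mlp": self.batchnorm_after_first_mlp,
            "batchnorm_momentum": self.batchnorm_momentum,
            "dropout_position": self.dropout_position,
            "dropout_rate": self.dropout_rate,
            "allow_non_tapered": self.allow_non_tapered,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("lstm_units", "mlp_units"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class LSTMCellWeights:
    """Per-gate LSTM weights: input matrices (units x input_dim), recurrent
    matrices (units x units) and bias vectors (units,)."""

    W_ix: np.ndarray
    W_fx: np.ndarray
    W_ox: np.ndarray
    W_cx: np.ndarray
    W_ia: np.ndarray
    W_fa: np.ndarray
    W_oa: np.ndarray
    W_ca: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        u, d = self.W_ix.shape
        for name in ("W_ix", "W_fx", "W_ox", "W_cx"):
            if getattr(self, name).shape != (u, d):
                raise ContractError(f"{name} must have shape ({u}, {d})")
        for name in ("W_ia", "W_fa", "W_oa", "W_ca"):
            if getattr(self, name).shape != (u, u):
                raise ContractError(f"{name} must have shape ({u}, {u})")
        for name in ("b_i", "b_f", "b_o", "b_c"):
            if getattr(self, name).shape != (u,):
                raise ContractError(f"{name} must have shape ({u},)")
        for name in self.__dataclass_fields__:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ContractError(f"{name} contains non-finite values")

    @property
    def units(self) -> int:
        return self.W_ix.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_ix.shape[1]

    @classmethod
    def random(cls, input_dim: int, units: int, rng: np.random.Generator,
               scale: float = 0.5) -> "LSTMCellWeights":
        def m(*shape):
            return rng.normal(0.0, scale, size=shape)
        return cls(
            W_ix=m(units, input_dim), W_fx=m(units, input_dim),
            W_ox=m(units, input_dim), W_cx=m(units, input_dim),
            W_ia=m(units, units), W_fa=m(units, units),
            W_oa=m(units, units), W_ca=m(units, units),
            b_i=m(units), b_f=m(units), b_o=m(units), b_c=m(units),
        )

    def to_fused(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Repack into the backend's fused (Wx, Wh, b) layout with gate
        blocks [input, forget, candidate, output]."""
        wx = np.concatenate([self.W_ix.T, self.W_fx.T, self.W_cx.T, self.W_ox.T], axis=1)
        wh = np.concatenate([self.W_ia.T, self.W_fa.T, self.W_ca.T, self.W_oa.T], axis=1)
        b = np.concatenate([self.b_i, self.b_f, self.b_c, self.b_o])
        return wx, wh, b


@dataclass(frozen=True)
class LayerDescriptor:
    kind: str  # "lstm" | "dense" | "batchnorm" | "dropout" | "output"
    fan_in: int
    fan_out: int
    activation: str | None
    n_trainable: int
    n_aux: int = 0


@dataclass
class ModelSpec:
    """Declarative layer-by-layer description of the built network."""

    config: NetworkConfig
    layers: list[LayerDescriptor] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(l.n_trainable + l.n_aux for l in self.layers)

    @property
    def trainable_params(self) -> int:
        return sum(l.n_trainable for l in self.layers)

    @property
    def aux_params(self) -> int:
        return sum(l.n_aux for l in self.layers)


# ---------------------------------------------------------------------------
# Reference cell (independent oracle)
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def lstm_cell_step(
    w: LSTMCellWeights, x_t: np.ndarray, a_prev: np.ndarray, c_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the standard LSTM cell, gate by gate.

    i, f, o are sigmoid gates on W_*x x_t + W_*a a_prev + b_*; the candidate
    is tanh with its own weights; c_t = f*c_prev + i*candidate and
    a_t = o * tanh(c_t).
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    a_prev = np.asarray(a_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    if x_t.shape != (w.input_dim,):
        raise ContractError(f"x_t must have shape ({w.input_dim},), got {x_t.shape}")
    if a_prev.shape != (w.units,) or c_prev.shape != (w.units,):
        raise ContractError(f"a_prev/c_prev must have shape ({w.units},)")
    i_t = _sigmoid(w.W_ix @ x_t + w.W_ia @ a_prev + w.b_i)
    f_t = _sigmoid(w.W_fx @ x_t + w.W_fa @ a_prev + w.b_f)
    o_t = _sigmoid(w.W_ox @ x_t + w.W_oa @ a_prev + w.b_o)
    g_t = np.tanh(w.W_cx @ x_t + w.W_ca @ a_prev + w.b_c)
    c_t = f_t * c_prev + i_t * g_t
    a_t = o_t * np.tanh(c_t)
    return a_t, c_t


def gru_memory_update(
    i_t: np.ndarray, c_prev: np.ndarray, a_prev: np.ndarray
) -> np.ndarray:
    """GRU-style memory update: c_t = (1 - i_t)*c_prev + i_t*a_prev."""
    i_t = np.asarray(i_t, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    a_prev = np.asarray(a_prev, dtype=np.float64)
    if not (i_t.shape == c_prev.shape == a_prev.shape):
        raise ContractError("i_t, c_prev, a_prev must share one shape")
    if np.any(i_t < 0) or np.any(i_t > 1):
        raise ContractError("gate values must lie in [0, 1]")
    return (1.0 - i_t) * c_prev + i_t * a_prev


def lstm_layer_forward(
    w: LSTMCellWeights, X: np.ndarray, return_sequence: bool = True
) -> np.ndarray:
    """Iterate :func:`lstm_cell_step` over t = 1..T from zero initial state.

    Returns the full (T, units) activation sequence, or only the final
    activation when ``return_sequence`` is false.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != w.input_dim:
        raise ContractError(f"X must be (T, {w.input_dim}), got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ContractError("X contains non-finite values")
    a = np.zeros(w.units)
    c = np.zeros(w.units)
    out = np.empty((X.shape[0], w.units))
    for t in range(X.shape[0]):
        a, c = lstm_cell_step(w, X[t], a, c)
        out[t] = a
    return out if return_sequence else a


# ---------------------------------------------------------------------------
# Network builder + parameter counter
# ---------------------------------------------------------------------------


def build_network(config: NetworkConfig) -> ModelSpec:
    """Layer descriptors for the bi-modular network (validation included in
    NetworkConfig construction)."""
    layers: list[LayerDescriptor] = []
    fan_in = config.input_dim
    for u in config.lstm_units:
        layers.append(LayerDescriptor(
            kind="lstm", fan_in=fan_in, fan_out=u, activation="tanh",
            n_trainable=4 * (u * fan_in + u * u + u),
        ))
        fan_in = u
    for k, u in enumerate(config.mlp_units, start=1):
        layers.append(LayerDescriptor(
            kind="dense", fan_in=fan_in, fan_out=u, activation="tanh",
            n_trainable=fan_in * u + u,
        ))
        fan_in = u
        if k == 1 and config.batchnorm_after_first_mlp:
            layers.append(LayerDescriptor(
                kind="batchnorm", fan_in=u, fan_out=u, activation=None,
                n_trainable=2 * u, n_aux=2 * u,
            ))
        if k == config.dropout_position and config.dropout_rate > 0:
            layers.append(LayerDescriptor(
                kind="dropout", fan_in=u, fan_out=u, activation=None,
                n_trainable=0,
            ))
    layers.append(LayerDescriptor(
        kind="output", fan_in=fan_in, fan_out=config.n_classes,
        activation="softmax", n_trainable=fan_in * config.n_classes + config.n_classes,
    ))
    return ModelSpec(config=config, layers=layers)


def count_parameters(config: NetworkConfig) -> int:
    """Closed-form total parameter count (trainable + batch-norm running
    statistics, matching the published accounting)."""
    total = 0
    d = config.input_dim
    for u in config.lstm_units:
        total += 4 * (u * d + u * u + u)
        d = u
    for k, u in enumerate(config.mlp_units, start=1):
        total += d * u + u
        d = u
        if k == 1 and config.batchnorm_after_first_mlp:
            total += 4 * u
    total += d * config.n_classes + config.n_classes
    return total


def build_model(
    config: NetworkConfig, seed: int = 0, dtype=np.float64
) -> _backend.SequentialModel:
    """Instantiate the network on the NumPy backend with seeded
    initialization (Glorot-uniform kernels, forget bias 1, zero-initialized
    output layer)."""
    rng = np.random.default_rng(seed)
    layers: list[_backend.Layer] = []
    fan_in = config.input_dim
    n_lstm = len(config.lstm_units)
    for j, u in enumerate(config.lstm_units):
        layers.append(_backend.LSTMLayer(
            fan_in, u, return_sequences=(j < n_lstm - 1), rng=rng, dtype=dtype,
        ))
        fan_in = u
    for k, u in enumerate(config.mlp_units, start=1):
        layers.append(_backend.DenseLayer(fan_in, u, "tanh", rng, dtype=dtype))
        fan_in = u
        if k == 1 and config.batchnorm_after_first_mlp:
            layers.append(_backend.BatchNormLayer(
                u, momentum=config.batchnorm_momentum, dtype=dtype,
            ))
        if k == config.dropout_position and config.dropout_rate > 0:
            layers.append(_backend.DropoutLayer(config.dropout_rate))
    layers.append(_backend.DenseLayer(
        fan_in, config.n_classes, None, rng, dtype=dtype, zero_init=True,
    ))
    model = _backend.SequentialModel(layers, config.input_dim, config.n_classes)
    model.config = config  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# Inference wrappers
# ---------------------------------------------------------------------------


def _as_batch(model: _backend.SequentialModel, features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        x = features.values[None, :, :]
    else:
        x = np.asarray(features)
        if x.ndim == 2:
            x = x[None, :, :]
    if x.ndim != 3 or x.shape[2] != model.input_dim:
        raise ContractError(
            f"feature width {x.shape[-1]} does not match model input_dim "
            f"{model.input_dim}"
        )
    return x


def forward(model: _backend.SequentialModel, features) -> np.ndarray:
    """Class probabilities for one FeatureMatrix (shape (n_classes,)) or a
    batch of feature matrices (shape (n, n_classes))."""
    x = _as_batch(model, features)
    probs = model.predict_proba(x)
    single = isinstance(features, FeatureMatrix) or np.asarray(features).ndim == 2
    return probs[0] if single else probs


def predict(model: _backend.SequentialModel, features) -> int | np.ndarray:
    """Argmax of :func:`forward`; ties broken by the lowest class index."""
    probs = forward(model, features)
    return int(np.argmax(probs)) if probs.ndim == 1 else np.argmax(probs, axis=1)
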