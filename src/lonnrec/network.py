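"""Feed-forward engine for logic-operator neural networks (LONNs).

A LONN sandwiches a block of *frozen* logic layers between two small trainable
layers:

    input (V1..V10)
      -> Dense ELU, trainable            (learns the parameter hierarchy)
      -> Dense squashing, frozen         (M-nodes: fixed "hypothesis" mixes)
      -> Dense squashing, frozen         (AND gates over M-node pairs)
      -> fixed OR stage, parameter-free  (disjunctions of AND outputs)
      -> Dense sigmoid, trainable        (outputs: therapy time, treatment key)

Gradients flow *through* the frozen layers by the chain rule but never update
them, so after any amount of training the logic block is bit-identical to its
initialisation.  Training is plain mini-batch ADAM on an MSE loss, implemented
here directly so that the frozen/trainable partition is explicit and auditable.

The default geometry (widths 10, 4, 3, 2; ``beta_int`` = 1.5) yields exactly
116 trainable and 59 non-trainable parameters; the all-trainable ReLU baseline
of the same silhouette has 293.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .exceptions import (
    DivergenceError,
    InvalidInputError,
    InvalidParameterError,
    SerializationError,
    ShapeError,
)
from .logic import gate_parameters

__all__ = [
    "DenseLayer",
    "LonnModel",
    "LonnSpec",
    "TrainConfig",
    "TrainingHistory",
    "build_dense_baseline",
    "build_lonn",
    "count_parameters",
    "load_model",
    "predict",
    "save_model",
    "train",
]

FORMAT_VERSION = 1

# ---------------------------------------------------------------------------
# Activations (value and derivative w.r.t. the pre-activation z)
# ---------------------------------------------------------------------------


def _act(name: str, z: np.ndarray, beta: Optional[float]) -> np.ndarray:
    if name == "linear":
        return z
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "elu":  # alpha = 1
        return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))
    if name == "sigmoid":
        return expit(z)
    if name == "squashing":
        b = float(beta)
        return (np.logaddexp(0.0, b * z) - np.logaddexp(0.0, b * (z - 1.0))) / b
    raise InvalidParameterError(f"unknown activation: {name!r}")


def _act_grad(name: str, z: np.ndarray, a: np.ndarray, beta: Optional[float]) -> np.ndarray:
    if name == "linear":
        return np.ones_like(z)
    if name == "relu":
        return (z > 0).astype(float)
    if name == "elu":
        return np.where(z > 0, 1.0, a + 1.0)
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "squashing":
        b = float(beta)
        return expit(b * z) - expit(b * (z - 1.0))
    raise InvalidParameterError(f"unknown activation: {name!r}")


_ACTIVATIONS = ("linear", "relu", "elu", "sigmoid", "squashing")


# ---------------------------------------------------------------------------
# Layers and model
# ---------------------------------------------------------------------------


@dataclass
class DenseLayer:
    """One fully connected layer ``a = sigma(x W^T + b)``.

    ``trainable=False`` marks frozen parameters; ``counted=False`` additionally
    excludes the layer from parameter counts (used for the fixed OR stage,
    whose unit weights are structural, not parameters).
    """

    weights: np.ndarray  # (out, in)
    biases: np.ndarray  # (out,)
    activation: str = "linear"
    beta: Optional[float] = None
    trainable: bool = True
    counted: bool = True
    name: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float).reshape(-1)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.biases.shape[0]:
            raise ShapeError("weights must be (out, in) matching biases (out,)")
        if self.activation not in _ACTIVATIONS:
            raise InvalidParameterError(f"unknown activation: {self.activation!r}")
        if self.activation == "squashing":
            if self.beta is None or float(self.beta) == 0.0:
                raise InvalidParameterError("squashing activation requires nonzero beta")

    @property
    def fan_in(self) -> int:
        return self.weights.shape[1]

    @property
    def fan_out(self) -> int:
        return self.weights.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.fan_in:
            raise ShapeError(
                f"layer {self.name or self.activation!r} expects {self.fan_in} inputs, "
                f"got shape {x.shape}"
            )
        z = x @ self.weights.T + self.biases
        return _act(self.activation, z, self.beta)


def dense_forward(layer: DenseLayer, inputs: Sequence[float]) -> np.ndarray:
    """Apply one layer to a single input vector (convenience wrapper)."""
    x = np.asarray(inputs, dtype=float).reshape(1, -1)
    return layer.forward(x)[0]


@dataclass
class LonnModel:
    """A stack of dense layers with an explicit frozen/trainable partition."""

    layers: List[DenseLayer]
    kind: str = "lonn"
    input_names: Optional[List[str]] = None

    @property
    def input_dim(self) -> int:
        return self.layers[0].fan_in

    @property
    def output_dim(self) -> int:
        return self.layers[-1].fan_out

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        if a.ndim == 1:
            a = a.reshape(1, -1)
        for layer in self.layers:
            a = layer.forward(a)
        return a

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    # -- internals used by training / gradient checks -----------------------

    def _forward_cached(self, X: np.ndarray):
        a = np.asarray(X, dtype=float)
        caches = []
        for layer in self.layers:
            z = a @ layer.weights.T + layer.biases
            out = _act(layer.activation, z, layer.beta)
            caches.append((a, z, out))
            a = out
        return a, caches

    def _backward(self, caches, dL_da: np.ndarray):
        """Return per-layer (dW, db) for trainable layers (None for frozen)."""
        grads: List[Optional[Tuple[np.ndarray, np.ndarray]]] = [None] * len(self.layers)
        grad = dL_da
        for idx in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[idx]
            x_in, z, a = caches[idx]
            dz = grad * _act_grad(layer.activation, z, a, layer.beta)
            if layer.trainable:
                grads[idx] = (dz.T @ x_in, dz.sum(axis=0))
            if idx > 0:
                grad = dz @ layer.weights
        return grads


def predict(model: LonnModel, X: np.ndarray) -> np.ndarray:
    """Forward pass; sigmoid head keeps outputs in (0, 1)."""
    return model.predict(X)


def count_parameters(model: LonnModel) -> Tuple[int, int]:
    """(trainable, non-trainable) parameter totals; uncounted stages are 0."""
    trainable = 0
    frozen = 0
    for layer in model.layers:
        if not layer.counted:
            continue
        n = layer.weights.size + layer.biases.size
        if layer.trainable:
            trainable += n
        else:
            frozen += n
    return trainable, frozen


# ---------------------------------------------------------------------------
# Reference architectures
# ---------------------------------------------------------------------------


@dataclass
class LonnSpec:
    """Geometry and seeds of the reference LONN.

    ``m_layer_width`` M-nodes each take a fixed convex mixture of the first
    layer's outputs; ``and_layer_width`` AND gates conjoin consecutive M-node
    pairs; the parameter-free OR stage produces ``or_stage_width`` disjunction
    values which feed the sigmoid head.  ``beta_int`` is the (fixed, shared)
    squashing slope of the logic block.
    """

    input_dim: int = 10
    first_layer_width: int = 10
    m_layer_width: int = 4
    and_layer_width: int = 3
    or_stage_width: int = 2
    output_dim: int = 2
    beta_int: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "input_dim",
            "first_layer_width",
            "m_layer_width",
            "and_layer_width",
            "or_stage_width",
            "output_dim",
        ):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be positive")
        if float(self.beta_int) == 0.0:
            raise InvalidParameterError("beta_int must be nonzero")
        if self.and_layer_width > self.m_layer_width - 1:
            raise InvalidParameterError(
                "and_layer_width must be at most m_layer_width - 1 "
                "(AND gates conjoin consecutive M-node pairs)"
            )
        if self.or_stage_width > self.and_layer_width:
            raise InvalidParameterError("or_stage_width must not exceed and_layer_width")


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def _or_stage_matrix(and_width: int, or_width: int) -> np.ndarray:
    """Fixed 0/1 disjunction groups: overlapping contiguous windows of AND outputs."""
    W = np.zeros((or_width, and_width))
    if or_width == 1:
        W[0, :] = 1.0
        return W
    edges = [round(j * (and_width - 1) / or_width) for j in range(or_width + 1)]
    edges[-1] = and_width - 1
    for j in range(or_width):
        W[j, edges[j] : edges[j + 1] + 1] = 1.0
    return W


def build_lonn(spec: Optional[LonnSpec] = None) -> LonnModel:
    """Build the reference LONN: trainable ELU layer, frozen M / AND layers,
    fixed OR stage, trainable sigmoid head.

    M-node weights are drawn once from ``Uniform(0, 1)`` (seeded), normalised
    per node to sum to one (a fixed convex aggregation), bias 0; AND gates use
    the nilpotent conjunction parameters over consecutive M-node pairs; the OR
    stage is an uncounted fixed disjunction wiring.
    """
    if spec is None:
        spec = LonnSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    first = DenseLayer(
        weights=_glorot(rng, spec.first_layer_width, spec.input_dim),
        biases=np.zeros(spec.first_layer_width),
        activation="elu",
        trainable=True,
        name="input_elu",
    )

    m_w = rng.uniform(0.0, 1.0, size=(spec.m_layer_width, spec.first_layer_width))
    m_w /= m_w.sum(axis=1, keepdims=True)
    m_layer = DenseLayer(
        weights=m_w,
        biases=np.zeros(spec.m_layer_width),
        activation="squashing",
        beta=spec.beta_int,
        trainable=False,
        name="m_nodes",
    )

    and_w = np.zeros((spec.and_layer_width, spec.m_layer_width))
    gate_w, gate_b = gate_parameters("AND", 2)
    for i in range(spec.and_layer_width):
        and_w[i, i : i + 2] = gate_w
    and_layer = DenseLayer(
        weights=and_w,
        biases=np.full(spec.and_layer_width, gate_b),
        activation="squashing",
        beta=spec.beta_int,
        trainable=False,
        name="and_gates",
    )

    or_stage = DenseLayer(
        weights=_or_stage_matrix(spec.and_layer_width, spec.or_stage_width),
        biases=np.zeros(spec.or_stage_width),
        activation="squashing",
        beta=spec.beta_int,
        trainable=False,
        counted=False,
        name="or_stage",
    )

    head = DenseLayer(
        weights=_glorot(rng, spec.output_dim, spec.or_stage_width),
        biases=np.zeros(spec.output_dim),
        activation="sigmoid",
        trainable=True,
        name="output_sigmoid",
    )

    return LonnModel(layers=[first, m_layer, and_layer, or_stage, head], kind="lonn")


def build_dense_baseline(
    input_dim: int = 10, output_dim: int = 2, seed: int = 0
) -> LonnModel:
    """All-trainable ReLU control network with the LONN silhouette.

    Hidden widths (10, 10, 4, 3, 2) with ReLU, then a sigmoid head; 293
    trainable parameters at the default dimensions.
    """
    if input_dim < 1 or output_dim < 1:
        raise InvalidParameterError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    widths = [input_dim, 10, 10, 4, 3, 2]
    layers = []
    for i in range(len(widths) - 1):
        layers.append(
            DenseLayer(
                weights=_glorot(rng, widths[i + 1], widths[i]),
                biases=np.zeros(widths[i + 1]),
                activation="relu",
                trainable=True,
                name=f"relu_{i}",
            )
        )
    layers.append(
        DenseLayer(
            weights=_glorot(rng, output_dim, widths[-1]),
            biases=np.zeros(output_dim),
            activation="sigmoid",
            trainable=True,
            name="output_sigmoid",
        )
    )
    return LonnModel(layers=layers, kind="dense")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Mini-batch ADAM hyperparameters (defaults: batch 50, lr 0.02, 100 epochs)."""

    learning_rate: float = 0.02
    batch_size: int = 50
    epochs: int = 100
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    shuffle_seed: int = 0


@dataclass
class TrainingHistory:
    """Per-epoch loss (MSE) and training error (MAE x 100 on normalised outputs)."""

    losses: List[float] = field(default_factory=list)
    training_errors: List[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.losses)


def train(
    model: LonnModel, X: np.ndarray, Y: np.ndarray, config: TrainConfig = TrainConfig()
) -> TrainingHistory:
    """Minimise mean squared error by mini-batch ADAM.

    The loss is averaged over samples and outputs.  Gradients propagate
    through frozen layers (their fixed weights enter the chain rule) but only
    trainable layers are updated.  The data order is reshuffled every epoch
    from ``shuffle_seed``; the last incomplete batch is used, not dropped.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ShapeError("X and Y must be 2-D")
    if X.shape[0] == 0:
        raise InvalidInputError("training data is empty")
    if X.shape[0] != Y.shape[0]:
        raise ShapeError("X and Y must have the same number of rows")
    if X.shape[1] != model.input_dim or Y.shape[1] != model.output_dim:
        raise ShapeError(
            f"model expects X (*, {model.input_dim}) and Y (*, {model.output_dim})"
        )

    n = X.shape[0]
    rng = np.random.default_rng(config.shuffle_seed)
    # ADAM state per trainable layer: (mW, vW, mb, vb)
    state = {}
    for idx, layer in enumerate(model.layers):
        if layer.trainable:
            state[idx] = [
                np.zeros_like(layer.weights),
                np.zeros_like(layer.weights),
                np.zeros_like(layer.biases),
                np.zeros_like(layer.biases),
            ]
    step = 0
    b1, b2, eps = config.adam_beta1, config.adam_beta2, config.adam_epsilon
    history = TrainingHistory()

    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = perm[start : start + config.batch_size]
            xb, yb = X[batch], Y[batch]
            pred, caches = model._forward_cached(xb)
            dL = 2.0 * (pred - yb) / pred.size
            grads = model._backward(caches, dL)
            step += 1
            for idx, g in enumerate(grads):
                if g is None:
                    continue
                dW, db = g
                mW, vW, mb, vb = state[idx]
                layer = model.layers[idx]
                mW *= b1
                mW += (1 - b1) * dW
                vW *= b2
                vW += (1 - b2) * dW * dW
                mb *= b1
                mb += (1 - b1) * db
                vb *= b2
                vb += (1 - b2) * db * db
                corr1 = 1 - b1**step
                corr2 = 1 - b2**step
                layer.weights -= (
                    config.learning_rate * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
                )
                layer.biases -= (
                    config.learning_rate * (mb / corr1) / (np.sqrt(vb / corr2) + eps)
                )
        pred = model.forward(X)
        loss = float(np.mean((Y - pred) ** 2))
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        history.losses.append(loss)
        history.training_errors.append(float(np.mean(np.abs(Y - pred))) * 100.0)
    return history


# ---------------------------------------------------------------------------
# Gradient-check helpers (used by the test suite; no training side effects)
# ---------------------------------------------------------------------------


def trainable_parameters_flat(model: LonnModel) -> np.ndarray:
    parts = []
    for layer in model.layers:
        if layer.trainable:
            parts.append(layer.weights.ravel())
            parts.append(layer.biases.ravel())
    return np.concatenate(parts) if parts else np.array([])


def set_trainable_parameters_flat(model: LonnModel, flat: np.ndarray) -> None:
    pos = 0
    for layer in model.layers:
        if layer.trainable:
            k = layer.weights.size
            layer.weights = flat[pos : pos + k].reshape(layer.weights.shape).copy()
            pos += k
            k = layer.biases.size
            layer.biases = flat[pos : pos + k].reshape(layer.biases.shape).copy()
            pos += k


def mse_loss(model: LonnModel, X: np.ndarray, Y: np.ndarray) -> float:
    pred = model.forward(np.asarray(X, dtype=float))
    return float(np.mean((np.asarray(Y, dtype=float) - pred) ** 2))


def mse_gradient_flat(model: LonnModel, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`mse_loss` w.r.t. the flat trainable vector."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    pred, caches = model._forward_cached(X)
    dL = 2.0 * (pred - Y) / pred.size
    grads = model._backward(caches, dL)
    parts = []
    for g in grads:
        if g is not None:
            parts.append(g[0].ravel())
            parts.append(g[1].ravel())
    return np.concatenate(parts) if parts else np.array([])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: LonnModel, path) -> None:
    """Write the model to a single JSON document (bit-exact round trip)."""
    doc = {
        "format_version": FORMAT_VERSION,
        "kind": model.kind,
        "input_names": model.input_names,
        "layers": [
            {
                "name": layer.name,
                "weights": layer.weights.tolist(),
                "biases": layer.biases.tolist(),
                "activation": layer.activation,
                "beta": layer.beta,
                "trainable": layer.trainable,
                "counted": layer.counted,
            }
            for layer in model.layers
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> LonnModel:
    """Read a model written by :func:`save_model`; never returns a partial model."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SerializationError(f"malformed model file: {exc}") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise SerializationError("malformed model file: missing field 'format_version'")
    if doc["format_version"] != FORMAT_VERSION:
        raise SerializationError(
            f"unsupported model format version {doc['format_version']!r} "
            f"(expected {FORMAT_VERSION})"
        )
    layers = []
    for i, spec in enumerate(doc.get("layers", [])):
        for fname in ("weights", "biases", "activation", "trainable"):
            if fname not in spec:
                raise SerializationError(f"layer {i}: missing field {fname!r}")
        layers.append(
            DenseLayer(
                weights=np.asarray(spec["weights"], dtype=float),
                biases=np.asarray(spec["biases"], dtype=float),
                activation=spec["activation"],
                beta=spec.get("beta"),
                trainable=bool(spec["trainable"]),
                counted=bool(spec.get("counted", True)),
                name=spec.get("name", ""),
            )
        )
    if not layers:
        raise SerializationError("malformed model file: no layers")
    return LonnModel(
        layers=layers, kind=doc.get("kind", "lonn"), input_names=doc.get("input_names")
    )
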