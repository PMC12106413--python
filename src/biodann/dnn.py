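"""Feed-forward regression network with exact reverse-mode gradients.

A plain multilayer perceptron (default two hidden layers of 64 ReLU units,
linear output) mapping a flattened feature window to the next-step target.
Training minimises batch-mean squared error with either plain gradient
descent (theta <- theta - eta * grad) or Adam; every stochastic choice
(initialisation, minibatch shuffling, input-noise augmentation) flows from
the run seed.  The :func:`train` loop is model-agnostic: anything exposing
``parameters()``, ``predict(X)`` and ``loss_and_grads(X, y)`` can be trained
with it (the attention encoder reuses it unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "LayerParams",
    "MLPModel",
    "TrainConfig",
    "LossHistory",
    "layer_forward",
    "mlp_forward",
    "grad_step",
    "backprop",
    "train",
]

ACTIVATIONS = ("relu", "sigmoid", "identity")


def _act(z: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "identity":
        return z
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(z: np.ndarray, a: np.ndarray, name: str) -> np.ndarray:
    # derivative w.r.t. pre-activation z, given the activation output a
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "identity":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class LayerParams:
    """One dense layer: output = f(W x + b)."""

    W: np.ndarray
    b: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.ndim != 1 or self.W.shape[0] != self.b.size:
            raise ValueError("W must be (out, in) and b (out,) with matching out")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")


def layer_forward(x: np.ndarray, layer: LayerParams) -> np.ndarray:
    """Apply ``f(W x + b)`` to a vector or a batch of row vectors."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != layer.W.shape[1]:
        raise ValueError(
            f"input dim {x.shape[-1]} does not match layer input {layer.W.shape[1]}"
        )
    return _act(x @ layer.W.T + layer.b, layer.activation)


@dataclass
class MLPModel:
    """Ordered dense layers; final layer is an identity-activated scalar head."""

    layers: list[LayerParams]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("model needs at least one layer")
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if nxt.W.shape[1] != prev.W.shape[0]:
                raise ValueError("consecutive layer dimensions do not chain")

    @property
    def input_dim(self) -> int:
        return self.layers[0].W.shape[1]

    @property
    def output_dim(self) -> int:
        return self.layers[-1].W.shape[0]

    @classmethod
    def create(
        cls,
        input_dim: int,
        hidden: Sequence[int] = (64, 64),
        activation: str = "relu",
        seed: int = 0,
    ) -> "MLPModel":
        """He-style scaled-uniform initialisation from the run seed."""
        rng = np.random.default_rng(seed)
        dims = [input_dim, *hidden, 1]
        layers = []
        for i, (d_in, d_out) in enumerate(zip(dims, dims[1:])):
            limit = np.sqrt(6.0 / d_in)
            W = rng.uniform(-limit, limit, size=(d_out, d_in))
            act = "identity" if i == len(dims) - 2 else activation
            layers.append(LayerParams(W=W, b=np.zeros(d_out), activation=act))
        return cls(layers=layers)

    # --- trainable-model protocol -------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend((layer.W, layer.b))
        return out

    def _flatten(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Scalar predictions for a batch; 3-d windows are flattened."""
        out = self._flatten(X)
        for layer in self.layers:
            out = layer_forward(out, layer)
        return out[:, 0]

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        return backprop(self, X, y)


def mlp_forward(x: np.ndarray, model: MLPModel) -> np.ndarray:
    """Forward pass for a single input vector."""
    out = np.asarray(x, dtype=float)
    for layer in model.layers:
        out = layer_forward(out, layer)
    return out


def grad_step(theta, grad, eta: float):
    """Plain gradient-descent update ``theta - eta * grad``.

    Accepts a single array or a list of arrays (applied elementwise).
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    if isinstance(theta, (list, tuple)):
        if len(theta) != len(grad):
            raise ValueError("theta and grad lengths differ")
        return [grad_step(t, g, eta) for t, g in zip(theta, grad)]
    theta = np.asarray(theta, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if theta.shape != grad.shape:
        raise ValueError("theta and grad shapes differ")
    return theta - eta * grad


def backprop(
    model: MLPModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    """Batch-mean-MSE loss and exact gradients for every W and b.

    Gradients are returned in the same order as ``model.parameters()``.
    """
    X = model._flatten(np.atleast_2d(np.asarray(X, dtype=float)))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("batch is empty")
    n = X.shape[0]

    activations = [X]
    pre = []
    out = X
    for layer in model.layers:
        z = out @ layer.W.T + layer.b
        out = _act(z, layer.activation)
        pre.append(z)
        activations.append(out)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite activations in forward pass")
    pred = out[:, 0]
    resid = pred - y
    loss = float(np.mean(resid**2))

    delta = (2.0 * resid / n)[:, None]  # dL/d(output activation)
    grads: list[np.ndarray] = []
    for i in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[i]
        dz = delta * _act_grad(pre[i], activations[i + 1], layer.activation)
        dW = dz.T @ activations[i]
        db = dz.sum(axis=0)
        grads.insert(0, db)
        grads.insert(0, dW)
        if i > 0:
            delta = dz @ layer.W
    return loss, grads


@dataclass
class TrainConfig:
    """Optimisation settings; defaults follow the standard configuration
    (learning rate 1e-3, batch 32, 100 epochs, Adam, MSE loss)."""

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    optimizer: str = "adam"
    loss: str = "mse"
    seed: int = 0
    augment_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("gd", "adam"):
            raise ValueError("optimizer must be 'gd' or 'adam'")
        if self.loss != "mse":
            raise ValueError("only mse loss is supported")
        if self.augment_noise_sd < 0:
            raise ValueError("augment_noise_sd must be >= 0")


@dataclass
class LossHistory:
    train: list[float] = field(default_factory=list)
    validation: list[float] = field(default_factory=list)


class TrainableModel(Protocol):
    def parameters(self) -> list[np.ndarray]: ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...
    def loss_and_grads(self, X, y) -> tuple[float, list[np.ndarray]]: ...


def _mse(model: TrainableModel, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((model.predict(X) - y) ** 2))


def train(
    model: TrainableModel,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> tuple[TrainableModel, LossHistory]:
    """Minibatch training loop (in place on the model's parameter arrays).

    Per epoch: seeded shuffle, optional Gaussian input augmentation, one
    update per minibatch, then a clean full-pass train/validation loss.
    Raises ``FloatingPointError`` if the loss goes non-finite.
    """
    X_tr, y_tr = (np.asarray(a, dtype=float) for a in train_set)
    X_val, y_val = (np.asarray(a, dtype=float) for a in val_set)
    if X_tr.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")

    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    history = LossHistory()

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    step = 0

    for epoch in range(config.epochs):
        order = rng.permutation(X_tr.shape[0])
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb = X_tr[idx]
            if config.augment_noise_sd > 0:
                Xb = Xb + rng.normal(0.0, config.augment_noise_sd, Xb.shape)
            loss, grads = model.loss_and_grads(Xb, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch start {start}"
                )
            if config.optimizer == "gd":
                for p, g in zip(params, grads):
                    p -= config.learning_rate * g
            else:
                step += 1
                for j, (p, g) in enumerate(zip(params, grads)):
                    m_state[j] = beta1 * m_state[j] + (1 - beta1) * g
                    v_state[j] = beta2 * v_state[j] + (1 - beta2) * g**2
                    m_hat = m_state[j] / (1 - beta1**step)
                    v_hat = v_state[j] / (1 - beta2**step)
                    p -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        history.train.append(_mse(model, X_tr, y_tr))
        history.validation.append(_mse(model, X_val, y_val))
    return model, history
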