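"""Minimal dense-network engine: He-uniform init, ReLU/sigmoid/softmax,
Adam, cross-entropy losses and plateau learning-rate reduction.

Shared by the activity-level MLP classifier and the tabular GAN.  Kept
deliberately small: fully-connected layers only, explicit forward/backward
passes, NumPy throughout, seeded initialization for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Dense", "Network", "Adam", "ReduceLROnPlateau",
           "binary_cross_entropy", "categorical_cross_entropy"]

_EPS = 1e-12


def _he_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Dense:
    """One fully-connected layer with a fused activation."""

    def __init__(self, fan_in: int, fan_out: int, activation: str, rng: np.random.Generator):
        if activation not in ("relu", "sigmoid", "linear", "softmax"):
            raise ValueError(f"unknown activation {activation!r}")
        self.W = _he_uniform(rng, fan_in, fan_out)
        self.b = np.zeros(fan_out)
        self.activation = activation
        self._x: np.ndarray | None = None
        self._z: np.ndarray | None = None
        self._a: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.W + self.b
        if self.activation == "relu":
            a = np.maximum(z, 0.0)
        elif self.activation == "sigmoid":
            a = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        elif self.activation == "softmax":
            e = np.exp(z - z.max(axis=1, keepdims=True))
            a = e / e.sum(axis=1, keepdims=True)
        else:
            a = z
        self._x, self._z, self._a = x, z, a
        return a

    def delta_from_dout(self, dout: np.ndarray) -> np.ndarray:
        """Gradient wrt the pre-activation, given the gradient wrt the output."""
        if self.activation == "relu":
            return dout * (self._z > 0)
        if self.activation == "sigmoid":
            return dout * self._a * (1.0 - self._a)
        if self.activation == "linear":
            return dout
        raise ValueError("softmax gradient must be fused with the loss")

    def backward(self, delta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """From the pre-activation gradient: (dW, db, dx)."""
        dW = self._x.T @ delta
        db = delta.sum(axis=0)
        dx = delta @ self.W.T
        return dW, db, dx


class Network:
    """A stack of Dense layers."""

    def __init__(self, layers: list[Dense]):
        self.layers = layers

    @classmethod
    def dense_stack(
        cls,
        widths: list[int],
        activations: list[str],
        seed: int = 0,
    ) -> "Network":
        """Build from layer widths ``[in, h1, ..., out]`` and per-layer activations."""
        if len(activations) != len(widths) - 1:
            raise ValueError("need one activation per layer")
        rng = np.random.default_rng(seed)
        layers = [
            Dense(widths[i], widths[i + 1], activations[i], rng)
            for i in range(len(widths) - 1)
        ]
        return cls(layers)

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, delta_last: np.ndarray) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
        """Backpropagate from the last layer's pre-activation gradient.

        Returns per-layer (dW, db) in forward order plus the gradient wrt
        the network input (used to chain a frozen discriminator onto a
        generator).
        """
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        delta = delta_last
        for i in reversed(range(len(self.layers))):
            dW, db, dx = self.layers[i].backward(delta)
            grads.append((dW, db))
            if i > 0:
                delta = self.layers[i - 1].delta_from_dout(dx)
            else:
                delta = dx  # gradient wrt the input itself
        grads.reverse()
        return grads, delta

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend((layer.W, layer.b))
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w


@dataclass
class Adam:
    """Adam optimizer (default config: α=0.001, β₁=0.9, β₂=0.999, ε=1e−8, decay 0)."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    decay: float = 0.0
    _m: list[np.ndarray] = field(default_factory=list)
    _v: list[np.ndarray] = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        lr = self.lr / (1.0 + self.decay * self._t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** self._t)
            vhat = v / (1 - self.beta2 ** self._t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    optimizer: Adam
    factor: float = 0.5
    patience: int = 10
    min_lr: float = 1e-6
    _best: float = np.inf
    _wait: int = 0

    def update(self, monitored: float) -> None:
        if monitored < self._best - 1e-12:
            self._best = monitored
            self._wait = 0
        else:
            self._wait += 1
            if self._wait > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self._wait = 0


def binary_cross_entropy(pred: np.ndarray, target: np.ndarray) -> float:
    p = np.clip(pred, _EPS, 1 - _EPS)
    return float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))


def categorical_cross_entropy(pred: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(pred, _EPS, 1.0)
    return float(-np.mean(np.sum(onehot * np.log(p), axis=1)))
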