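"""Minimal dense neural-network core: layers, Adam, and common losses.

Everything is float32 numpy. Networks are small (a few dense layers on
flattened image patches), so explicit forward/backward passes written
against BLAS-backed matmuls are fast enough for CPU training at the
problem sizes this package targets.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Sequential",
    "Adam",
    "smooth_l1",
    "smooth_l1_grad",
    "bce_with_logits",
    "bce_with_logits_grad",
]


class Dense:
    """Affine layer ``y = x @ W + b`` with He-normal initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.W = (rng.standard_normal((in_dim, out_dim)) * scale).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    @property
    def params(self):
        return []

    @property
    def grads(self):
        return []


class Sequential:
    """A plain layer stack with weight get/set for target-network syncing."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        own = self.params
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


class Adam:
    """Adaptive-moment optimizer over a fixed parameter list."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def smooth_l1(pred: np.ndarray, target: np.ndarray) -> float:
    """Huber loss with delta=1, averaged over all elements."""
    d = pred - target
    a = np.abs(d)
    per = np.where(a < 1.0, 0.5 * d * d, a - 0.5)
    return float(per.mean())


def smooth_l1_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    d = pred - target
    g = np.clip(d, -1.0, 1.0)
    return (g / d.size).astype(np.float32)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, target: np.ndarray) -> float:
    """Numerically stable binary cross-entropy on raw scores."""
    z = logits.astype(np.float64)
    loss = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


def bce_with_logits_grad(logits: np.ndarray, target: np.ndarray) -> np.ndarray:
    g = _sigmoid(logits) - target
    return (g / g.size).astype(np.float32)
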