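"""Minimal dense-network building blocks with explicit backprop.

Just enough machinery for the two small networks in this package: the
variational topic-model encoder and the amortized mixture-parameter network.
Parameters are plain float64 ndarrays; every layer caches its forward inputs
and exposes ``backward`` returning the gradient w.r.t. its input.  Adam keeps
per-array moment state keyed by parameter identity.
"""

from __future__ import annotations

import numpy as np


class Dense:
    """Affine layer with He-scaled Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale: float | None = None):
        s = np.sqrt(2.0 / n_in) if scale is None else scale
        self.W = rng.normal(0.0, s, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MLP:
    """Stack of Dense layers with ReLU between them (none after the last)."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.layers: list = []
        for k in range(len(sizes) - 1):
            self.layers.append(Dense(sizes[k], sizes[k + 1], rng))
            if k < len(sizes) - 2:
                self.layers.append(ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        out = []
        for layer in self.layers:
            if isinstance(layer, Dense):
                out.extend(layer.params)
        return out


class Adam:
    """Adam on a list of (param, grad) ndarray pairs, updated in place."""

    def __init__(self, lr: float = 1e-2, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params) -> None:
        self.t += 1
        for p, g in params:
            key = id(p)
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(y: np.ndarray, grad: np.ndarray, axis: int = -1) -> np.ndarray:
    """Gradient through softmax given its output y and upstream grad."""
    dot = (grad * y).sum(axis=axis, keepdims=True)
    return y * (grad - dot)


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))
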