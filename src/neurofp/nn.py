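"""Minimal feed-forward neural-network stack on numpy.

Implements exactly what the fingerprinting models need: dense layers,
batch normalization, ReLU, L2 normalization, softmax cross-entropy,
and the Adam optimizer.  The networks here are small (hundreds of inputs,
two hidden layers), so explicit numpy forward/backward passes are fast
and keep the package dependency-light and bit-reproducible under a seed.

Conventions: inputs are (batch, features); ``forward(x, train=...)``
caches what ``backward(grad)`` needs; parameter and gradient arrays are
exposed in matching order for the optimizer.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Dense",
    "BatchNorm",
    "ReLU",
    "L2Normalize",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
]


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    """Affine map with He-initialized weights."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.w.shape[0]:
            raise ValueError(
                f"input has {x.shape[1]} features, layer expects {self.w.shape[0]}"
            )
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward before forward"
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.gw, self.gb]


class BatchNorm(Layer):
    """Batch normalization with running statistics for inference."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._std: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean = self.running_mean
            var = self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        if train:
            self._xhat = xhat
            self._std = std
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._xhat is not None and self._std is not None
        xhat = self._xhat
        self.ggamma[...] = (grad * xhat).sum(axis=0)
        self.gbeta[...] = grad.sum(axis=0)
        # standard batch-norm backward through batch statistics
        gx = (
            self.gamma
            / self._std
            * (grad - grad.mean(axis=0) - xhat * (grad * xhat).mean(axis=0))
        )
        return gx

    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def grads(self) -> list[np.ndarray]:
        return [self.ggamma, self.gbeta]


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return grad * self._mask


class L2Normalize(Layer):
    """Row-wise projection onto the unit sphere."""

    def __init__(self, eps: float = 1e-12) -> None:
        self.eps = eps
        self._y: np.ndarray | None = None
        self._norm: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        norm = np.sqrt((x * x).sum(axis=1, keepdims=True)) + self.eps
        y = x / norm
        if train:
            self._y = y
            self._norm = norm
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._y is not None and self._norm is not None
        y = self._y
        return (grad - y * (grad * y).sum(axis=1, keepdims=True)) / self._norm


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    logits: np.ndarray, labels: np.ndarray, binary: bool = False
) -> tuple[float, np.ndarray]:
    """Softmax cross-entropy (mean over the batch) and its gradient w.r.t.
    the logits.

    ``binary=True`` evaluates per-class binary cross-entropy against the
    one-hot targets over the softmax outputs, for strict comparability
    with formulations phrased that way; the categorical form is the
    default.
    """
    b = logits.shape[0]
    probs = softmax(logits)
    onehot = np.zeros_like(probs)
    onehot[np.arange(b), labels] = 1.0
    eps = 1e-12
    if binary:
        loss = -np.mean(
            onehot * np.log(probs + eps) + (1 - onehot) * np.log(1 - probs + eps)
        ) * probs.shape[1]
        # gradient through softmax of the summed per-class BCE
        dprobs = (-onehot / (probs + eps) + (1 - onehot) / (1 - probs + eps)) / b
        dots = (dprobs * probs).sum(axis=1, keepdims=True)
        grad = probs * (dprobs - dots)
    else:
        loss = float(-np.log(probs[np.arange(b), labels] + eps).mean())
        grad = (probs - onehot) / b
    return float(loss), grad
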