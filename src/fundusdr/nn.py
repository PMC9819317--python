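"""Minimal NumPy neural-network engine: conv / max-pool / dense layers,
softmax cross-entropy, and a Nadam optimizer.

Layers operate on NHWC float64 tensors.  Convolutions are 'same'-padded
3x3 stride-1 via im2col; pooling is 2x2 stride 2.  Activations are
:class:`~fundusdr.activations.ActivationSpec` objects supplying both the
forward map (with its safety clamp) and the analytic derivative, so the
backward pass is exact for every registered activation.

Everything is deterministic given the seed; there is no threading or
stochastic kernel choice.
"""

from __future__ import annotations

import numpy as np

from .activations import ActivationSpec

__all__ = ["Conv2D", "MaxPool2D", "Flatten", "Dense", "ActLayer",
           "Sequential", "Nadam", "softmax", "softmax_xent"]


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W, kh*kw*C) patch matrix for stride-1 'same' conv."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, h, w, kh, kw, c),
        strides=(s[0], s[1], s[2], s[1], s[2], s[3]),
    )
    return view.reshape(n, h, w, kh * kw * c)


class Conv2D:
    """3x3 stride-1 'same' convolution with bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.W = np.zeros((kernel * kernel * c_in, c_out))
        self.b = np.zeros(c_out)

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.k * self.k * self.c_in
        fan_out = self.k * self.k * self.c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=self.W.shape)
        self.b = np.zeros(self.c_out)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = _im2col(x, self.k, self.k, self.k // 2)
        return self._cols @ self.W + self.b

    def backward(self, grad: np.ndarray):
        n, h, w, _ = grad.shape
        cols = self._cols.reshape(-1, self.W.shape[0])
        g = grad.reshape(-1, self.c_out)
        self.dW = cols.T @ g
        self.db = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, h, w, self.k, self.k, self.c_in)
        pad = self.k // 2
        dx = np.zeros((n, h + 2 * pad, w + 2 * pad, self.c_in))
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dx[:, pad:pad + h, pad:pad + w, :]

    def grads(self):
        return [self.dW, self.db]


class MaxPool2D:
    """2x2 stride-2 max pooling; gradient routed to the argmax."""

    def __init__(self, size: int = 2):
        self.size = size

    n_params = 0

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"pool size {s} does not divide input {h}x{w}")
        xr = x.reshape(n, h // s, s, w // s, s, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // s, w // s, c, s * s)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return xr.max(axis=-1)

    def backward(self, grad: np.ndarray):
        n, ho, wo, c = grad.shape
        s = self.size
        dx = np.zeros((n, ho, wo, c, s * s))
        np.put_along_axis(dx, self._argmax[..., None], grad[..., None], axis=-1)
        dx = dx.reshape(n, ho, wo, c, s, s).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(self._in_shape)


class Flatten:
    n_params = 0

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray):
        return grad.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int):
        self.n_in, self.n_out = n_in, n_out
        self.W = np.zeros((n_in, n_out))
        self.b = np.zeros(n_out)

    def init(self, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (self.n_in + self.n_out))
        self.W = rng.uniform(-limit, limit, size=self.W.shape)
        self.b = np.zeros(self.n_out)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def grads(self):
        return [self.dW, self.db]


class ActLayer:
    """Elementwise activation layer backed by an ActivationSpec."""

    def __init__(self, spec: ActivationSpec):
        self.spec = spec

    n_params = 0

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return self.spec.apply(x)

    def backward(self, grad: np.ndarray):
        return grad * self.spec.grad(self._x)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def init(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if hasattr(layer, "init"):
                layer.init(rng)

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. logits.

    No epsilon floor: a true-class probability that underflows to 0 yields
    an infinite loss, which callers treat as divergence.
    """
    p = softmax(logits)
    n = logits.shape[0]
    with np.errstate(divide="ignore"):
        loss = float(-np.log(p[np.arange(n), labels]).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Nadam:
    """Nadam: Adam with Nesterov momentum (Dozat 2016, Keras-style bias
    correction with the momentum term corrected one step ahead)."""

    def __init__(self, params: list[np.ndarray], lr: float = 2e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = (b1 * m / (1 - b1 ** (self.t + 1))
                     + (1 - b1) * g / (1 - b1 ** self.t))
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def clip_grad_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    total = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total
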