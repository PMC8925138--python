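"""Minimal numpy layers with explicit forward/backward passes.

The trainable head of the pipeline is small and fixed in shape, so rather
than a general autograd graph each layer caches what its backward pass needs.
Layers operate on channels-last tensors: 2-D convolutions take ``(H, W, C)``,
linear layers take ``(N, C)``.  Convolutions use 'same' zero padding and
arbitrary dilation via im2col.  Gradient correctness is checked by finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self):
        self.grad[...] = 0.0


def he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator,
                 dtype=np.float32, prefix: str = "linear"):
        self.w = Param(f"{prefix}.w", he_init(rng, (din, dout), din, dtype))
        self.b = Param(f"{prefix}.b", np.zeros(dout, dtype=dtype))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv2d(Layer):
    """2-D convolution on (H, W, Cin) with 'same' padding and dilation."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dilation: int = 1, dtype=np.float32, prefix: str = "conv"):
        self.cin, self.cout, self.k, self.dilation = cin, cout, k, dilation
        fan_in = k * k * cin
        self.w = Param(f"{prefix}.w", he_init(rng, (fan_in, cout), fan_in, dtype))
        self.b = Param(f"{prefix}.b", np.zeros(cout, dtype=dtype))
        self._col = None
        self._shape = None

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x):
        h, w, cin = x.shape
        k, d = self.k, self.dilation
        if k == 1:
            return x.reshape(h * w, cin)
        pad = d * (k // 2)
        xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
        cols = np.empty((h, w, k * k, cin), dtype=x.dtype)
        for a in range(k):
            for b in range(k):
                cols[:, :, a * k + b, :] = xp[a * d : a * d + h, b * d : b * d + w, :]
        return cols.reshape(h * w, k * k * cin)

    def forward(self, x):
        self._shape = x.shape
        h, w, _ = x.shape
        col = self._im2col(x)
        self._col = col
        y = col @ self.w.value + self.b.value
        return y.reshape(h, w, self.cout)

    def backward(self, dy):
        h, w, cin = self._shape
        k, d = self.k, self.dilation
        dyf = dy.reshape(h * w, self.cout)
        self.w.grad += self._col.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcol = dyf @ self.w.value.T
        if k == 1:
            return dcol.reshape(h, w, cin)
        pad = d * (k // 2)
        dxp = np.zeros((h + 2 * pad, w + 2 * pad, cin), dtype=dy.dtype)
        dcol = dcol.reshape(h, w, k * k, cin)
        for a in range(k):
            for b in range(k):
                dxp[a * d : a * d + h, b * d : b * d + w, :] += dcol[:, :, a * k + b, :]
        return dxp[pad : pad + h, pad : pad + w, :]


class InstanceNorm(Layer):
    """Per-channel normalization over the two spatial axes, learned affine."""

    def __init__(self, channels: int, dtype=np.float32, eps: float = 1e-5,
                 prefix: str = "inorm"):
        self.eps = eps
        self.gamma = Param(f"{prefix}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Param(f"{prefix}.beta", np.zeros(channels, dtype=dtype))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        h, w, _ = x.shape
        mu = x.mean(axis=(0, 1), keepdims=True)
        var = x.var(axis=(0, 1), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, h * w)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, n = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.value
        # standard normalization backward over the spatial axes
        return inv * (
            dxhat
            - dxhat.mean(axis=(0, 1), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 1), keepdims=True)
        )


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class ResidualBlock(Layer):
    """Pre-activation block: IN -> ReLU -> Conv3x3 -> ReLU -> Conv3x3 -> +skip.

    Both convolutions share the block's dilation rate.
    """

    def __init__(self, channels: int, dilation: int, rng: np.random.Generator,
                 dtype=np.float32, prefix: str = "block"):
        self.body = Sequential([
            InstanceNorm(channels, dtype=dtype, prefix=f"{prefix}.inorm"),
            ReLU(),
            Conv2d(channels, channels, 3, rng, dilation=dilation, dtype=dtype,
                   prefix=f"{prefix}.conv1"),
            ReLU(),
            Conv2d(channels, channels, 3, rng, dilation=dilation, dtype=dtype,
                   prefix=f"{prefix}.conv2"),
        ])
        self.dilation = dilation

    def params(self):
        return self.body.params()

    def forward(self, x):
        return x + self.body.forward(x)

    def backward(self, dy):
        return dy + self.body.backward(dy)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class RAdam:
    """Rectified Adam (variance-warmup Adam) on a list of Params."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self):
        self.t += 1
        b1t, b2t = self.beta1**self.t, self.beta2**self.t
        rho = self.rho_inf - 2.0 * self.t * b2t / (1.0 - b2t)
        if rho > 5.0:
            r = np.sqrt(
                ((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho)
            )
        else:
            r = None
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad.astype(np.float64)
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            mhat = m / (1.0 - b1t)
            if r is not None:
                vhat = np.sqrt(v / (1.0 - b2t)) + self.eps
                upd = self.lr * r * mhat / vhat
            else:
                upd = self.lr * mhat
            p.value -= upd.astype(p.value.dtype)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
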