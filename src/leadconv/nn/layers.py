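"""Minimal 1-D neural-network layers with explicit backpropagation.

Activations are ``float32`` arrays in channel-first layout
``(channels, batch, length)`` (``(batch, features)`` for :class:`Linear`).
The channel-first layout keeps every im2col gather and scatter a
contiguous block copy, which is what makes the convolutions fast in pure
numpy.  Every layer caches what its backward pass needs during ``forward``
and accumulates parameter gradients into ``Param.grad``.  The set of
layers is exactly what the 1-D encoder-decoder architectures require:
convolution (same padding), batch normalisation, ReLU/tanh, max-pooling,
linear-interpolation upsampling and fully-connected maps.  Correctness is
pinned by numerical gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A learnable array and its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        """Non-learnable persistent state (e.g. batch-norm running stats)."""
        return {}


class Conv1d(Layer):
    """Same-padding 1-D convolution (odd kernel), im2col + GEMM.

    Input ``(c_in, batch, length)`` -> output ``(c_out, batch, length)``.
    The weight is stored as ``(c_out, c_in * k)`` so the forward pass is a
    single GEMM against a ``(c_in * k, batch * length)`` column matrix.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        std = np.sqrt(2.0 / (c_in * kernel_size))
        self.W = Param(rng.normal(0.0, std, size=(c_out, c_in * kernel_size)))
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        c, n, length = x.shape
        p = self.k // 2
        xp = np.zeros((c, n, length + 2 * p), dtype=DTYPE)
        xp[:, :, p:p + length] = x
        cols = np.empty((c, self.k, n, length), dtype=DTYPE)
        for t in range(self.k):
            cols[:, t] = xp[:, :, t:t + length]
        return cols.reshape(c * self.k, n * length)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c, n, length = x.shape
        cols = self._im2col(x)
        y = self.W.data @ cols + self.b.data[:, None]
        if train:
            self._cols, self._shape = cols, (c, n, length)
        return y.reshape(self.c_out, n, length)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, length = self._shape
        dyf = dy.reshape(self.c_out, n * length)
        self.W.grad += dyf @ self._cols.T
        self.b.grad += dyf.sum(axis=1)
        dcols = (self.W.data.T @ dyf).reshape(c, self.k, n, length)
        p = self.k // 2
        dxp = np.zeros((c, n, length + 2 * p), dtype=DTYPE)
        for t in range(self.k):
            dxp[:, :, t:t + length] += dcols[:, t]
        self._cols = None
        return dxp[:, :, p:p + length]

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, length);
    channel-first input ``(channels, batch, length)``."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g = self.gamma.data[:, None, None]
        b = self.beta.data[:, None, None]
        if train:
            mean = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[:, None, None]) * inv[:, None, None]
            self._cache = (xhat, inv)
            return (g * xhat + b).astype(DTYPE)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[:, None, None]) * inv[:, None, None]
        return (g * xhat + b).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = dy.shape[1] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2))
        self.beta.grad += dy.sum(axis=(1, 2))
        dxhat = dy * self.gamma.data[:, None, None]
        s1 = dxhat.sum(axis=(1, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
        return (inv[:, None, None] / m) * (m * dxhat - s1 - xhat * s2)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU(Layer):
    def forward(self, x, train):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class Tanh(Layer):
    def forward(self, x, train):
        y = np.tanh(x)
        if train:
            self._y = y
        return y

    def backward(self, dy):
        return dy * (1.0 - self._y * self._y)


class MaxPool1d(Layer):
    """Max-pooling with factor 2 along the last axis (length must be even)."""

    def forward(self, x, train):
        *lead, length = x.shape
        if length % 2:
            raise ValueError("max-pool input length must be even")
        xr = x.reshape(*lead, length // 2, 2)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy):
        *lead, length = self._shape
        dxr = np.zeros((*lead, length // 2, 2), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(*lead, length)


class UpsampleLinear(Layer):
    """Length-doubling linear-interpolation upsampling.

    ``y[2i] = x[i]``; ``y[2i+1] = (x[i] + x[i+1]) / 2`` with edge clamping
    at the right boundary.
    """

    def forward(self, x, train):
        *lead, length = x.shape
        y = np.empty((*lead, 2 * length), dtype=DTYPE)
        y[:, :, 0::2] = x
        y[:, :, 1:-1:2] = 0.5 * (x[:, :, :-1] + x[:, :, 1:])
        y[:, :, -1] = x[:, :, -1]
        if train:
            self._len = length
        return y

    def backward(self, dy):
        length = self._len
        dx = dy[:, :, 0::2].copy()
        dodd = dy[:, :, 1::2]
        dx[:, :, :-1] += 0.5 * dodd[:, :, :length - 1]
        dx[:, :, 1:] += 0.5 * dodd[:, :, :length - 1]
        dx[:, :, -1] += dodd[:, :, -1]
        return dx


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, std, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        self._x = None
        return dy @ self.W.data.T

    def params(self):
        return [self.W, self.b]


class Chain(Layer):
    """Sequential composition of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.state().items():
                out[f"{i}.{key}"] = val
        return out
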