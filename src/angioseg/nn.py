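"""Minimal trainable 3D convolution stack on numpy.

Layers operate on channels-last tensors ``(N, D, H, W, C)`` so every
convolution reduces to BLAS matmuls over the channel axis. Each layer caches
what its backward pass needs; gradients accumulate into ``Param.grad``.
This is deliberately a small, fully deterministic engine sized for
desk-scale volumes, not a general autodiff framework.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _he_std(fan_in: int, negative_slope: float) -> float:
    return float(np.sqrt(2.0 / (fan_in * (1.0 + negative_slope ** 2))))


class Conv1x1(Layer):
    """Pointwise convolution: a matmul over the channel axis."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 negative_slope: float = 0.1, zero_init: bool = False):
        std = 0.0 if zero_init else _he_std(cin, negative_slope)
        self.w = Param(rng.normal(0.0, std, (cin, cout)) if std else np.zeros((cin, cout)))
        self.b = Param(np.zeros(cout))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, dy):
        x = self._x
        self.w.grad += np.tensordot(x, dy, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        self.b.grad += dy.sum(axis=(0, 1, 2, 3))
        return dy @ self.w.data.T


class Conv3x3(Layer):
    """3x3x3 convolution, stride 1, zero 'same' padding.

    Implemented as 27 shifted pointwise matmuls to avoid im2col copies.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 negative_slope: float = 0.1):
        std = _he_std(27 * cin, negative_slope)
        self.w = Param(rng.normal(0.0, std, (3, 3, 3, cin, cout)))
        self.b = Param(np.zeros(cout))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, d, h, w_, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        self._xp = xp
        y = np.broadcast_to(self.b.data, (n, d, h, w_, self.b.data.shape[0])).copy()
        for a in range(3):
            for b in range(3):
                for c3 in range(3):
                    xs = xp[:, a:a + d, b:b + h, c3:c3 + w_, :]
                    y += xs @ self.w.data[a, b, c3]
        return y

    def backward(self, dy):
        xp = self._xp
        n, d, h, w_, _ = dy.shape
        dxp = np.zeros_like(xp)
        for a in range(3):
            for b in range(3):
                for c3 in range(3):
                    xs = xp[:, a:a + d, b:b + h, c3:c3 + w_, :]
                    self.w.grad[a, b, c3] += np.tensordot(
                        xs, dy, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
                    dxp[:, a:a + d, b:b + h, c3:c3 + w_, :] += dy @ self.w.data[a, b, c3].T
        self.b.grad += dy.sum(axis=(0, 1, 2, 3))
        return dxp[:, 1:-1, 1:-1, 1:-1, :]


class DownConv(Layer):
    """Convolutional downsampling unit: kernel 2, stride 2 (halves each axis)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 negative_slope: float = 0.1):
        std = _he_std(8 * cin, negative_slope)
        self.w = Param(rng.normal(0.0, std, (8 * cin, cout)))
        self.b = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    @staticmethod
    def _to_cols(x):
        n, d, h, w_, c = x.shape
        r = x.reshape(n, d // 2, 2, h // 2, 2, w_ // 2, 2, c)
        r = r.transpose(0, 1, 3, 5, 2, 4, 6, 7)
        return np.ascontiguousarray(r).reshape(n, d // 2, h // 2, w_ // 2, 8 * c)

    def forward(self, x):
        if any(s % 2 for s in x.shape[1:4]):
            raise ValueError(f"spatial dims {x.shape[1:4]} not divisible by 2")
        cols = self._to_cols(x)
        self._cols = cols
        return cols @ self.w.data + self.b.data

    def backward(self, dy):
        cols = self._cols
        self.w.grad += np.tensordot(cols, dy, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        self.b.grad += dy.sum(axis=(0, 1, 2, 3))
        dcols = dy @ self.w.data.T
        n, d2, h2, w2, c8 = dcols.shape
        c = c8 // 8
        r = dcols.reshape(n, d2, h2, w2, 2, 2, 2, c).transpose(0, 1, 4, 2, 5, 3, 6, 7)
        return np.ascontiguousarray(r).reshape(n, d2 * 2, h2 * 2, w2 * 2, c)


class UpConv(Layer):
    """Transposed-convolution upsampling unit: kernel 2, stride 2 (doubles axes)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 negative_slope: float = 0.1):
        std = _he_std(cin, negative_slope)
        self.w = Param(rng.normal(0.0, std, (cin, 8 * cout)))
        self.b = Param(np.zeros(cout))
        self._x: np.ndarray | None = None
        self._cout = cout

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        t = x @ self.w.data
        n, d, h, w_, _ = t.shape
        c = self._cout
        r = t.reshape(n, d, h, w_, 2, 2, 2, c).transpose(0, 1, 4, 2, 5, 3, 6, 7)
        y = np.ascontiguousarray(r).reshape(n, d * 2, h * 2, w_ * 2, c)
        return y + self.b.data

    def backward(self, dy):
        n, d2, h2, w2, c = dy.shape
        self.b.grad += dy.sum(axis=(0, 1, 2, 3))
        r = dy.reshape(n, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2, c)
        r = r.transpose(0, 1, 3, 5, 2, 4, 6, 7)
        dt = np.ascontiguousarray(r).reshape(n, d2 // 2, h2 // 2, w2 // 2, 8 * c)
        self.w.grad += np.tensordot(self._x, dt, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        return dt @ self.w.data.T


class LeakyReLU(Layer):
    """f(x) = x for x >= 0, slope * x for x < 0 (slope default 0.1)."""

    def __init__(self, negative_slope: float = 0.1):
        self.slope = float(negative_slope)
        self._pos: np.ndarray | None = None

    def forward(self, x):
        pos = x >= 0
        self._pos = pos
        return np.where(pos, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._pos, dy, self.slope * dy)


class Sigmoid(Layer):
    """Numerically stable logistic: e^x / (e^x + 1)."""

    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x):
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (ex + 1.0)
        self._y = y
        return y

    def backward(self, dy):
        y = self._y
        return dy * y * (1.0 - y)


class SGD:
    """SGD with momentum and decoupled-from-nothing classic weight decay:
    ``v <- mu v - lr (g + wd p); p <- p + v``.
    """

    def __init__(self, params: list[Param], momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad.fill(0.0)

    def step(self, lr: float):
        for p, v in zip(self.params, self._v):
            np.multiply(v, self.momentum, out=v)
            v -= lr * (p.grad + self.weight_decay * p.data)
            p.data += v
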