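"""Minimal NumPy neural-network backend.

Implements exactly the layers the conditional generator/discriminator
pair needs — dense, 2-D convolution (im2col + BLAS matmul), batch
normalization, nearest-neighbour upsampling, ReLU/LeakyReLU/Tanh — each
with a hand-written backward pass, plus the Adam optimizer and
binary-cross-entropy-with-logits.  Everything runs in float32; forward
passes cache what backward needs, so the usage pattern is strictly
forward -> backward -> update.

Tensors are NCHW.  Layers are deterministic: randomness enters only
through the RNG used at weight initialization.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Layer", "Dense", "Conv2d", "BatchNorm", "ReLU",
           "LeakyReLU", "Tanh", "Upsample2x", "Reshape", "Sequential",
           "Adam", "bce_with_logits"]

F32 = np.float32


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, 0.02, (d_out, d_in)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, gout):
        self.w.grad += gout.T @ self._x
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value


class Conv2d(Layer):
    """k x k convolution via im2col; stride 1 'same' or strided 'valid'."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, stride: int = 1, pad: int = 1,
                 bias: bool = True):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, 0.02, (c_out, c_in * k * k)))
        self.b = Param(np.zeros(c_out)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (n, c, ho, wo, k, k) -> (n*ho*wo, c*k*k)
        self._ho, self._wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n * self._ho * self._wo, c * k * k)
        self._cols, self._xshape = cols, x.shape
        y = cols @ self.w.value.T
        if self.b is not None:
            y += self.b.value
        return np.ascontiguousarray(
            y.reshape(n, self._ho, self._wo, self.c_out)
            .transpose(0, 3, 1, 2))

    def backward(self, gout):
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = self._xshape
        ho, wo = self._ho, self._wo
        g = gout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        self.w.grad += g.T @ self._cols
        if self.b is not None:
            self.b.grad += g.sum(axis=0)
        dcols = (g @ self.w.value).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (n, c, ho, wo, k, k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm(Layer):
    """Batch normalization over 2-D (N, D) or 4-D (N, C, H, W) input."""

    def __init__(self, dim: int, rng: np.random.Generator,
                 momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(rng.normal(1.0, 0.02, dim))
        self.beta = Param(np.zeros(dim))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(dim, dtype=F32)
        self.running_var = np.ones(dim, dtype=F32)

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1, 1)

    def forward(self, x, train=True):
        shp = self._shape(x)
        if train:
            axes = self._axes(x)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        self._xhat, self._inv, self._train = xhat, inv, train
        return self.gamma.value.reshape(shp) * xhat \
            + self.beta.value.reshape(shp)

    def backward(self, gout):
        shp = self._shape(gout)
        axes = self._axes(gout)
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        g = gout * self.gamma.value.reshape(shp)
        if not self._train:
            return g * inv.reshape(shp)
        gm = g.mean(axis=axes).reshape(shp)
        gxm = (g * xhat).mean(axis=axes).reshape(shp)
        return inv.reshape(shp) * (g - gm - xhat * gxm)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._pos = x > 0
        return x * self._pos

    def backward(self, gout):
        return gout * self._pos


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self._pos = x > 0
        return np.where(self._pos, x, self.slope * x)

    def backward(self, gout):
        return np.where(self._pos, gout, F32(self.slope) * gout)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gout):
        return gout * (1.0 - self._y**2)


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gout):
        n, c, h, w = gout.shape
        return gout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = shape

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, gout):
        return gout.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, gout):
        for lay in reversed(self.layers):
            gout = lay.backward(gout)
        return gout


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 beta_1: float = 0.5, beta_2: float = 0.999,
                 epsilon: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta_1, beta_2, epsilon
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def bce_with_logits(logits: np.ndarray, target: float):
    """Mean binary cross-entropy on raw logits; returns (loss, dlogits).

    Numerically stable form: max(x,0) - x*t + log(1 + exp(-|x|)).
    """
    x = logits.ravel().astype(np.float64)
    t = float(target)
    loss = float(np.mean(np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))))
    sig = 1.0 / (1.0 + np.exp(-x))
    grad = ((sig - t) / x.size).reshape(logits.shape)
    return loss, grad.astype(F32)
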