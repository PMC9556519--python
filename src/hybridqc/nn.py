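"""Minimal CPU neural-network engine for the 3D QC classifier.

Layers operate on float32 numpy arrays in channels-last (NDHWC)
layout -- the memory order that keeps the im2col gather contiguous on
CPU -- and implement explicit forward/backward passes, so gradients
with respect to the *input* are available exactly, which is what
integrated-gradients attribution needs.  Convolution is an im2col
matrix product; batch normalization follows the Keras convention
(trainable scale + shift, non-trainable moving statistics, eps 1e-3,
momentum 0.99).

Only what the QC network requires is implemented: 3x3x3 same-padding
convolution, 2x2x2 max pooling, batch normalization, ReLU, dropout,
global average pooling, dense layers, and an Adam optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv3D",
    "MaxPool3D",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "GlobalAvgPool3D",
    "Dense",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]

_F32 = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad


class Layer:
    """Base class: trainable layers expose aligned params/grads lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, same padding, He-initialized.

    Implemented as a sum of 27 shifted matrix products -- one (C_in x
    C_out) weight block per kernel offset -- instead of materializing
    an im2col matrix; this keeps peak memory at the size of the padded
    input and feeds BLAS near-contiguous operands.  The flat weight
    matrix has shape (27 * C_in, C_out) with row index
    offset * C_in + channel.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        k = 27 * c_in
        scale = np.sqrt(2.0 / k)
        self.w = (scale * rng.standard_normal((k, c_out))).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out
        self._xp = None
        self._cols = None
        self._shape = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    @staticmethod
    def _offsets():
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    yield i, j, k

    def _im2col(self, xp, n, d, h, w, c):
        """Patch matrix (N*D*H*W, 27*C) for the few-channel path.

        For each (i, j) the three k-shifts x C channels form one
        contiguous 3C-float run in the padded input, so nine strided
        views fill the matrix with streaming copies.
        """
        cols = np.empty((n, d, h, w, 9, 3 * c), dtype=_F32)
        sn, sd, sh, sw, sc = xp.strides
        for g, (i, j) in enumerate((i, j) for i in range(3) for j in range(3)):
            view = np.lib.stride_tricks.as_strided(
                xp[:, i:, j:, :, :],
                shape=(n, d, h, w, 3 * c),
                strides=(sn, sd, sh, sw, sc),
            )
            cols[:, :, :, :, g, :] = view
        return cols.reshape(n * d * h * w, 27 * c)

    def forward(self, x, training=False):
        n, d, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        self._shape = x.shape
        if c <= 8:
            cols = self._im2col(xp, n, d, h, w, c)
            out = cols @ self.w + self.b
            self._cols = cols if training else None
            self._xp = None
        else:
            wr = self.w.reshape(27, c, self.c_out)
            out = np.tile(self.b, (n * d * h * w, 1))
            for o, (i, j, k) in enumerate(self._offsets()):
                v = xp[:, i : i + d, j : j + h, k : k + w, :].reshape(-1, c)
                out += v @ wr[o]
            self._xp = xp if training else None
            self._cols = None
        return out.reshape(n, d, h, w, self.c_out)

    def backward(self, dout):
        n, d, h, w, c = self._shape
        dflat = dout.reshape(n * d * h * w, self.c_out)
        wr = self.w.reshape(27, c, self.c_out)
        self.db[...] = dflat.sum(axis=0)
        dxp = np.zeros((n, d + 2, h + 2, w + 2, c), dtype=_F32)
        if self._cols is not None:
            self.dw[...] = self._cols.T @ dflat
            self._cols = None
            dcols = (dflat @ self.w.T).reshape(n, d, h, w, 27, c)
            for o, (i, j, k) in enumerate(self._offsets()):
                dxp[:, i : i + d, j : j + h, k : k + w, :] += dcols[
                    :, :, :, :, o, :
                ]
        else:
            dwr = self.dw.reshape(27, c, self.c_out)
            for o, (i, j, k) in enumerate(self._offsets()):
                v = self._xp[:, i : i + d, j : j + h, k : k + w, :].reshape(-1, c)
                dwr[o] = v.T @ dflat
                dxp[:, i : i + d, j : j + h, k : k + w, :] += (
                    dflat @ wr[o].T
                ).reshape(n, d, h, w, c)
            self._xp = None
        return dxp[:, 1:-1, 1:-1, 1:-1, :]

    def input_gradient_pass(self, dout):
        """Backward variant that skips weight gradients (attribution)."""
        n, d, h, w, c = self._shape
        dflat = dout.reshape(n * d * h * w, self.c_out)
        dxp = np.zeros((n, d + 2, h + 2, w + 2, c), dtype=_F32)
        if c <= 8:
            dcols = (dflat @ self.w.T).reshape(n, d, h, w, 27, c)
            for o, (i, j, k) in enumerate(self._offsets()):
                dxp[:, i : i + d, j : j + h, k : k + w, :] += dcols[
                    :, :, :, :, o, :
                ]
        else:
            wr = self.w.reshape(27, c, self.c_out)
            for o, (i, j, k) in enumerate(self._offsets()):
                dxp[:, i : i + d, j : j + h, k : k + w, :] += (
                    dflat @ wr[o].T
                ).reshape(n, d, h, w, c)
        return dxp[:, 1:-1, 1:-1, 1:-1, :]


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2; extents must be even."""

    def __init__(self):
        self._argmax = None
        self._shape = None

    def forward(self, x, training=False):
        n, d, h, w, c = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("max pooling requires even spatial extents")
        xr = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(
            n, d // 2, h // 2, w // 2, c, 8
        )
        self._argmax = xr.argmax(axis=-1)
        self._shape = (n, d, h, w, c)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, d, h, w, c = self._shape
        dxr = np.zeros((n, d // 2, h // 2, w // 2, c, 8), dtype=_F32)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, d // 2, h // 2, w // 2, c, 2, 2, 2)
        return dxr.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(n, d, h, w, c)


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis.

    Trainable gamma/beta; moving mean/var are buffers excluded from
    the trainable-parameter count.
    """

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.99):
        self.gamma = np.ones(channels, dtype=_F32)
        self.beta = np.zeros(channels, dtype=_F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.moving_mean = np.zeros(channels, dtype=_F32)
        self.moving_var = np.ones(channels, dtype=_F32)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean[...] = (
                self.momentum * self.moving_mean + (1 - self.momentum) * mean
            )
            self.moving_var[...] = (
                self.momentum * self.moving_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.moving_mean, self.moving_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        xhat = ((x - mean) * inv_std).astype(_F32)
        self._cache = (xhat, inv_std, axes, training)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv_std, axes, training = self._cache
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        if not training:
            return (dout * (self.gamma * inv_std)).astype(_F32)
        dxhat = dout * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv_std
        return dx.astype(_F32)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_F32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class GlobalAvgPool3D(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dout):
        n, d, h, w, c = self._shape
        return np.broadcast_to(
            dout[:, None, None, None, :] / (d * h * w), self._shape
        ).astype(_F32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (scale * rng.standard_normal((n_in, n_out))).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return (dout @ self.w.T).astype(_F32)

    def input_gradient_pass(self, dout):
        return (dout @ self.w.T).astype(_F32)


class Adam:
    """Adam optimizer over a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.layers = [l for l in layers if l.params()]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for l in self.layers for p in l.params()]
        self.v = [np.zeros_like(p) for l in self.layers for p in l.params()]

    def step(self):
        self.t += 1
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params(), layer.grads()):
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
                mhat = self.m[i] / (1 - self.beta1**self.t)
                vhat = self.v[i] / (1 - self.beta2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
                i += 1
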