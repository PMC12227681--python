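"""Minimal CPU tensor layers for the distance-regression U-Net.

Everything runs on float32 numpy arrays in NHWC layout. Convolutions are
im2col + BLAS matmul; each layer caches what its analytic backward pass needs.
The implementation is deliberately small: exactly the layer set the network
uses (3x3 and 1x1 convolution, batch norm, ReLU, 2x2 max pooling, channel
dropout, 4x4/stride-2/pad-1 transposed convolution) and nothing else.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return (cols, out_h, out_w); cols has shape (N*OH*OW, C*k*k)."""
    n, h, w, c = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    v = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, H', W', C, k, k)
    v = v[:, ::stride, ::stride]
    oh, ow = v.shape[1], v.shape[2]
    cols = np.ascontiguousarray(v).reshape(n * oh * ow, c * k * k)
    return cols, oh, ow


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            oh: int, ow: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add column gradients back to the input."""
    n, h, w, c = x_shape
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=F32)
    d = dcols.reshape(n, oh, ow, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, i:i + oh * stride:stride, j:j + ow * stride:stride, :] += d[..., i, j]
    if pad:
        return dxp[:, pad:-pad, pad:-pad, :]
    return dxp


class Layer:
    """Base: layers expose params() -> list of (name, value, grad) triples."""

    def params(self):
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution with zero padding; weight shape (Cin, k, k, Cout)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_in, k, k, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train=False, rng=None):
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.k, 1, self.pad)
        self._cols = cols if train else None
        y = cols @ self.W.reshape(-1, self.c_out) + self.b
        return y.reshape(x.shape[0], oh, ow, self.c_out)

    def backward(self, dy):
        n, oh, ow, _ = dy.shape
        dyf = dy.reshape(-1, self.c_out)
        self.dW[...] = (self._cols.T @ dyf).reshape(self.W.shape)
        self.db[...] = dyf.sum(axis=0)
        dcols = dyf @ self.W.reshape(-1, self.c_out).T
        self._cols = None
        return _col2im(dcols, self._x_shape, self.k, 1, self.pad, oh, ow)


class ConvTranspose2D(Layer):
    """4x4 transposed convolution, stride 2, zero-padding 1 (doubles H, W).

    Implemented as zero-stuffing followed by an ordinary convolution with the
    spatially flipped kernel; the backward pass reuses the same im2col
    machinery on the stuffed input.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        self.k, self.stride, self.pad = 4, 2, 1
        self.c_in, self.c_out = c_in, c_out
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * self.k * self.k / (self.stride ** 2)
        self.W = (rng.standard_normal((c_in, self.k, self.k, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def _stuff(self, x):
        n, h, w, c = x.shape
        # stuffed grid padded by (k - 1 - pad) = 2 on each side
        xs = np.zeros((n, 2 * h + 3, 2 * w + 3, c), dtype=F32)
        xs[:, 2:2 * h + 1:2, 2:2 * w + 1:2, :] = x
        return xs

    def forward(self, x, train=False, rng=None):
        self._x_shape = x.shape
        xs = self._stuff(x)
        self._xs_shape = xs.shape
        cols, oh, ow = _im2col(xs, self.k, 1, 0)
        self._cols = cols if train else None
        wf = self.W[:, ::-1, ::-1, :].reshape(-1, self.c_out)
        y = cols @ wf + self.b
        return y.reshape(x.shape[0], oh, ow, self.c_out)

    def backward(self, dy):
        n, oh, ow, _ = dy.shape
        dyf = dy.reshape(-1, self.c_out)
        dwf = (self._cols.T @ dyf).reshape(self.W.shape)
        self.dW[...] = dwf[:, ::-1, ::-1, :]
        self.db[...] = dyf.sum(axis=0)
        wf = self.W[:, ::-1, ::-1, :].reshape(-1, self.c_out)
        dcols = dyf @ wf.T
        dxs = _col2im(dcols, self._xs_shape, self.k, 1, 0, oh, ow)
        self._cols = None
        h, w = self._x_shape[1], self._x_shape[2]
        return np.ascontiguousarray(dxs[:, 2:2 * h + 1:2, 2:2 * w + 1:2, :])


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
            self._invstd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
            self._xhat = ((x - mean) * self._invstd).astype(F32)
            self._m = x.shape[0] * x.shape[1] * x.shape[2]
            return self.gamma * self._xhat + self.beta
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        return (self.gamma * invstd) * (x - self.running_mean) + self.beta

    def backward(self, dy):
        xhat, invstd, m = self._xhat, self._invstd, self._m
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 1, 2))
        self.dbeta[...] = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma
        dx = (invstd / m) * (m * dxhat - dxhat.sum(axis=(0, 1, 2))
                             - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))
        self._xhat = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2x2(Layer):
    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        v = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        v = v.reshape(n, h // 2, w // 2, c, 4)
        idx = v.argmax(axis=-1)
        if train:
            self._idx, self._x_shape = idx, x.shape
        return np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._x_shape
        dv = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(dv, self._idx[..., None], dy[..., None], axis=-1)
        dv = dv.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._idx = None
        return np.ascontiguousarray(dv.reshape(n, h, w, c))


class Dropout(Layer):
    """Inverted elementwise dropout; identity at inference."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.uniform(size=x.shape) >= self.p).astype(F32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if not hasattr(self, "_mask") or self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class Adam:
    """Adam over a flat list of (name, value, grad) parameter triples."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (_, val, grad) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad * grad
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            val -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(val.dtype)
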