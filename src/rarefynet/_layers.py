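"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the refinement network needs: 2-D convolution with dilation and
'same' zero padding on a fixed 3x3 spatial field, batch normalisation, ELU /
ReLU, dropout, global average pooling, dense layers and a 3x3 average pool.
Arrays are channel-first ``(N, C, H, W)`` float64.

Each layer owns ``params`` (trainable) and ``state`` (non-trainable, e.g.
batch-norm running statistics) dictionaries; ``backward`` stores gradients in
``grads`` keyed like ``params`` and returns the gradient w.r.t. the input.
"""

from __future__ import annotations

import math

import numpy as np


class Layer:
    """Base class: stateless pass-through."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2d(Layer):
    """f x f convolution with dilation and zero padding that preserves H x W.

    Padding width is ``dilation * (f // 2)`` so every output position sees a
    full (possibly zero-padded) receptive field; with f=3, dilation=2 the
    effective footprint is 5x5.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd to preserve the 3x3 field")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        # He initialisation, appropriate for the ELU family
        weight = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                            (out_channels, in_channels, kernel_size, kernel_size))
        self.params = {"weight": weight, "bias": np.zeros(out_channels)}
        self._pad = dilation * (kernel_size // 2)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(C*f*f, N*H*W) patch matrix for a single-GEMM convolution."""
        n, c, h, w = x.shape
        f, d, p = self.kernel_size, self.dilation, self._pad
        xp = np.zeros((c, n, h + 2 * p, w + 2 * p), dtype=x.dtype)
        xp[:, :, p:p + h, p:p + w] = x.transpose(1, 0, 2, 3)
        rows = np.arange(f)[:, None] * d + np.arange(h)[None, :]   # (f, h)
        cols = np.arange(f)[:, None] * d + np.arange(w)[None, :]   # (f, w)
        # (c, f, f, n, h, w) -> flatten taps and batch/space
        gathered = xp[:, :, rows[:, None, :, None], cols[None, :, None, :]]
        gathered = gathered.transpose(0, 2, 3, 1, 4, 5)
        return np.ascontiguousarray(gathered).reshape(c * f * f, n * h * w)

    def forward(self, x, training=False, rng=None):
        self._x_shape = x.shape
        n, c, h, w = x.shape
        if self.kernel_size == 1:   # pointwise conv: plain channel matmul
            self._cols = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(c, -1)
        else:
            self._cols = self._im2col(x)
        w2 = self.params["weight"].reshape(self.out_channels, -1)
        y = (w2 @ self._cols).reshape(self.out_channels, n, h, w)
        return y.transpose(1, 0, 2, 3) + self.params["bias"][None, :, None, None]

    def backward(self, dy):
        n, _, h, w = self._x_shape
        c = self.in_channels
        f, d, p = self.kernel_size, self.dilation, self._pad
        dy2 = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(self.out_channels, -1)
        self.grads["weight"] = (dy2 @ self._cols.T).reshape(self.params["weight"].shape)
        self.grads["bias"] = dy2.sum(axis=1)
        w2 = self.params["weight"].reshape(self.out_channels, -1)
        if f == 1:
            return (w2.T @ dy2).reshape(c, n, h, w).transpose(1, 0, 2, 3)
        dcols = (w2.T @ dy2).reshape(c, f, f, n, h, w)
        dxp = np.zeros((c, n, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
        for a in range(f):
            for b in range(f):
                dxp[:, :, a * d:a * d + h, b * d:b * d + w] += dcols[:, a, b]
        return dxp[:, :, p:p + h, p:p + w].transpose(1, 0, 2, 3)


class BatchNorm2d(Layer):
    """Per-channel batch normalisation; inference uses running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.state = {"running_mean": np.zeros(channels), "running_var": np.ones(channels)}

    def forward(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.state["running_mean"] = (1 - m) * self.state["running_mean"] + m * mu
            self.state["running_var"] = (1 - m) * self.state["running_var"] + m * var
            self._invstd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu[None, :, None, None]) * self._invstd[None, :, None, None]
            self._training = True
        else:
            invstd = 1.0 / np.sqrt(self.state["running_var"] + self.eps)
            self._xhat = (x - self.state["running_mean"][None, :, None, None]) \
                * invstd[None, :, None, None]
            self._invstd = invstd
            self._training = False
        return self.params["gamma"][None, :, None, None] * self._xhat \
            + self.params["beta"][None, :, None, None]

    def backward(self, dy):
        axes = (0, 2, 3)
        xhat = self._xhat
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        gamma = self.params["gamma"]
        dxhat = dy * gamma[None, :, None, None]
        if not self._training:
            return dxhat * self._invstd[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        # batch-stat corrections reuse the reductions above:
        # sum(dxhat) = gamma * dbeta, sum(dxhat * xhat) = gamma * dgamma
        s1 = (gamma * dbeta)[None, :, None, None]
        s2 = (gamma * dgamma)[None, :, None, None]
        return (self._invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False, rng=None):
        # y = max(x, 0) + alpha * expm1(min(x, 0))
        neg = np.minimum(x, 0)
        em = np.expm1(neg, out=neg)
        if self.alpha != 1.0:
            em *= self.alpha
        self._slope = np.where(x > 0, np.asarray(1.0, dtype=x.dtype), em + self.alpha)
        return np.maximum(x, 0) + em

    def backward(self, dy):
        return dy * self._slope


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, dy):
        return dy * self._pos


class Dropout(Layer):
    """Inverted dropout; identity at inference or when p == 0."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            rng = np.random.default_rng()
        u = rng.random(x.shape, dtype=x.dtype if x.dtype == np.float32 else np.float64)
        self._mask = (u >= self.p) / np.asarray(1.0 - self.p, dtype=x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C), the mean of each feature map."""

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class AvgPool2dSame(Layer):
    """3x3 average pooling, stride 1, zero padding, padded cells counted.

    A fixed linear smoothing used by the pooling inception branch.
    """

    def __init__(self, kernel_size: int = 3):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.kernel_size = kernel_size

    @staticmethod
    def _shift(x: np.ndarray, di: int, dj: int) -> np.ndarray:
        h, w = x.shape[-2:]
        out = np.zeros_like(x)
        i0, i1 = max(0, -di), min(h, h - di)
        j0, j1 = max(0, -dj), min(w, w - dj)
        if i0 < i1 and j0 < j1:
            out[..., i0:i1, j0:j1] = x[..., i0 + di:i1 + di, j0 + dj:j1 + dj]
        return out

    def forward(self, x, training=False, rng=None):
        k = self.kernel_size // 2
        acc = np.zeros_like(x)
        for di in range(-k, k + 1):
            for dj in range(-k, k + 1):
                acc += self._shift(x, di, dj)
        return acc / self.kernel_size ** 2

    def backward(self, dy):
        k = self.kernel_size // 2
        acc = np.zeros_like(dy)
        for di in range(-k, k + 1):
            for dj in range(-k, k + 1):
                acc += self._shift(dy, -di, -dj)
        return acc / self.kernel_size ** 2


class Dense(Layer):
    """Fully connected layer on (N, features) arrays, Glorot-uniform init."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        limit = math.sqrt(6.0 / (in_features + out_features))
        self.params = {
            "weight": rng.uniform(-limit, limit, (in_features, out_features)),
            "bias": np.zeros(out_features),
        }

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, dy):
        self.grads["weight"] = self._x.T @ dy
        self.grads["bias"] = dy.sum(axis=0)
        return dy @ self.params["weight"].T
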