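"""Minimal CPU neural-network layers with explicit forward/backward passes.

All layers operate on arrays in NCHW layout (batch, channels, height, width)
and float32 precision.  Each layer owns its parameters and gradients in
``params`` / ``grads`` dicts keyed by short names ("W", "b", ...); a
:class:`~ichseg.nn.network.Module` tree exposes them under dotted paths so
that checkpoints and weight transfer can address tensors by name.

Convolutions use stride-1 "same" padding via im2col/col2im; up-sampling uses
a kernel-2 stride-2 transposed convolution.  This is deliberately a small,
deterministic core: no autograd graph, no GPU, seeded Kaiming-uniform init.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Linear",
    "GlobalAvgPool",
]


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Layer:
    """Base class: a parametric operation with an explicit backward pass."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for stride-1 convolution."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, Ho, Wo, k, k)
    n, c, ho, wo = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k
    )


def _col2im(dcol: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    dcol = dcol.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += dcol[:, :, :, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    """Stride-1 convolution with "same" zero padding (odd kernel)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("Conv2d supports odd kernels only (same padding)")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        self.params["W"] = kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        col = _im2col(x, self.k, self.pad)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        out = col @ wmat.T + self.params["b"]
        self._cache = (col, x.shape)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        col, x_shape = self._cache
        n, _, h, w = x_shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.grads["W"] = (dmat.T @ col).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        dcol = dmat @ self.params["W"].reshape(self.out_ch, -1)
        return _col2im(dcol, x_shape, self.k, self.pad)


class ConvTranspose2d(Layer):
    """Kernel-2 stride-2 transposed convolution: doubles H and W."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["W"] = kaiming_uniform(rng, (in_ch, out_ch, 2, 2), in_ch * 4)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        self._x = x
        y = np.einsum("ncij,cfab->nfiajb", x, self.params["W"], optimize=True)
        y = y.reshape(n, self.out_ch, 2 * h, 2 * w)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dout):
        x = self._x
        n, c, h, w = x.shape
        d6 = dout.reshape(n, self.out_ch, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
        # d6: (n, f, i, j, a, b)
        self.grads["W"] = np.einsum("ncij,nfijab->cfab", x, d6, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        return np.einsum("nfijab,cfab->ncij", d6, self.params["W"], optimize=True)


class BatchNorm2d(Layer):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.n_ch, self.momentum, self.eps = n_ch, momentum, eps
        self.params["gamma"] = np.ones(n_ch, dtype=np.float32)
        self.params["beta"] = np.zeros(n_ch, dtype=np.float32)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.last_batch_mean = mean
            self.last_batch_var = var
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, dout):
        xhat, inv, training, shape = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None] * inv[None, :, None, None]
        if not training:
            return dout * g
        n = shape[0] * shape[2] * shape[3]
        dxhat = dout * self.params["gamma"][None, :, None, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2 (even spatial sizes only)."""

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial size, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params["W"] = kaiming_uniform(rng, (out_dim, in_dim), in_dim)
        self.params["b"] = np.zeros(out_dim, dtype=np.float32)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial average."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)
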