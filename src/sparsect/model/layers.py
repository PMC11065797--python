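"""Minimal NumPy CNN layers with explicit forward/backward passes.

NCHW layout throughout; stride-1 same-padded convolutions only, which is
all the U-Net needs. Each layer instance caches what its backward pass
requires, so a layer object must not be reused twice within one forward
graph traversal.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base: trainable parameters live in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2d(Layer):
    """k x k convolution, stride 1, same padding (odd k)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        bias: bool,
        rng: np.random.Generator,
        init_scale: float = 1.0,
    ) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("only odd kernel sizes are supported")
        self.k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * kernel_size * kernel_size
        std = init_scale * np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.params["W"] = rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size)).astype(DTYPE)
        if bias:
            self.params["b"] = np.zeros(out_channels, dtype=DTYPE)
        self._cache_windows: np.ndarray | None = None

    @staticmethod
    def _correlate(xp: np.ndarray, kernel: np.ndarray, max_bytes: int = 1 << 27) -> np.ndarray:
        """Valid cross-correlation of padded input with (O, C, k, k) kernel.

        Chunks over output rows so the materialized window tensor stays
        below ``max_bytes`` (tensordot copies the sliding view).
        """
        k = kernel.shape[-1]
        n, c, hp, wp = xp.shape
        h, w = hp - k + 1, wp - k + 1
        out = np.empty((n, kernel.shape[0], h, w), dtype=xp.dtype)
        bytes_per_row = max(1, n * c * w * k * k * xp.itemsize)
        rows = max(1, max_bytes // bytes_per_row)
        for h0 in range(0, h, rows):
            h1 = min(h, h0 + rows)
            win = sliding_window_view(xp[:, :, h0 : h1 + k - 1, :], (k, k), axis=(2, 3))
            y = np.tensordot(win, kernel, axes=([1, 4, 5], [1, 2, 3]))
            out[:, :, h0:h1] = y.transpose(0, 3, 1, 2)
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        y = self._correlate(xp, self.params["W"])
        if "b" in self.params:
            y += self.params["b"][None, :, None, None]
        self._cache_windows = xp if training else None
        return y.astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._cache_windows
        if xp is None:
            raise RuntimeError("backward called without a training forward pass")
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        self.grads["W"] = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2, 3))
        p = self.k // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
        # gradient w.r.t. input: correlate with the flipped, transposed kernel
        w_flip = np.ascontiguousarray(self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        dx = self._correlate(dyp, w_flip)
        self._cache_windows = None
        return dx.astype(DTYPE, copy=False)


class BatchNorm2d(Layer):
    """Channelwise batch normalization with running statistics.

    ``affine=False`` (no learned scale/shift) matches the parameter-count
    convention pinned by the published architecture total; running mean and
    variance are kept as non-trainable state either way.
    """

    def __init__(self, channels: int, affine: bool, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.channels = channels
        self.affine = affine
        self.momentum = momentum
        self.eps = eps
        if affine:
            self.params["gamma"] = np.ones(channels, dtype=DTYPE)
            self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std)
        y = xhat
        if self.affine:
            y = y * self.params["gamma"][None, :, None, None] + self.params["beta"][None, :, None, None]
        return y.astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a training forward pass")
        xhat, inv_std = self._cache
        if self.affine:
            self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
            self.grads["beta"] = dy.sum(axis=(0, 2, 3))
            dxhat = dy * self.params["gamma"][None, :, None, None]
        else:
            dxhat = dy
        # standard batch-norm gradient
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        dx = inv_std[None, :, None, None] * (term1 - term2 - term3)
        self._cache = None
        return dx.astype(DTYPE, copy=False)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called without a training forward pass")
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._argmax = idx
            self._in_shape = x.shape
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._argmax is None or self._in_shape is None:
            raise RuntimeError("backward called without a training forward pass")
        n, c, h, w = self._in_shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        dx = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        self._argmax = None
        self._in_shape = None
        return np.ascontiguousarray(dx)


class UpsampleNearest2x2(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adaptive-moment estimation over a flat list of (layer, name) params."""

    def __init__(self, layers: list[Layer], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.slots = [(layer, name) for layer in layers for name in layer.params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads.get(name)
            if g is None:
                continue
            g = g.astype(DTYPE, copy=False)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            layer.params[name] -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
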