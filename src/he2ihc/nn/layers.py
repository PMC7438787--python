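"""Minimal CNN building blocks (forward + backward) on float32 numpy arrays.

All spatial tensors are NCHW.  Each layer owns its parameters in ``params``
(name -> array) and accumulates gradients of the same shapes in ``grads``.
``forward(x, train=True)`` caches whatever the backward pass needs; with
``train=False`` nothing is cached (and batch norm uses its running moments),
so evaluation and dense inference stay memory-light.

Convolution is im2col + matmul; its input gradient is assembled by a small
loop over kernel offsets with strided slice-adds, which avoids the very slow
scatter-add of a naive col2im.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "Linear"]


def _pad_hw(x: np.ndarray, p: int, value: float = 0.0) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=value)


def conv_out_size(size: int, kernel: int, stride: int, pad: int) -> int:
    """Output length of a conv/pool along one axis: floor((n + 2p - k)/s) + 1."""
    n = (size + 2 * pad - kernel) // stride + 1
    if n < 1:
        raise ValueError(
            f"window {kernel} (stride {stride}, pad {pad}) does not fit input of size {size}"
        )
    return n


class Layer:
    """Base class: a parameterised, differentiable module."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def _windows(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(N, C, Ho, Wo, k, k) view of all kernel windows of a padded input."""
    w = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


class Conv2d(Layer):
    """2-D convolution (cross-correlation), optional bias, He-normal init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.pad = pad
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.params["W"] = rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel)).astype(
            np.float32
        )
        if bias:
            self.params["b"] = np.zeros(out_channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s, p = self.kernel, self.stride, self.pad
        ho = conv_out_size(h, k, s, p)
        wo = conv_out_size(w, k, s, p)
        xp = _pad_hw(x, p)
        cols = np.ascontiguousarray(_windows(xp, k, s).transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        wmat = self.params["W"].reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if "b" in self.params:
            out += self.params["b"]
        if train:
            self._cache = (cols, x.shape, (ho, wo))
        else:
            self._cache = None
        return out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        n, c, h, w = x_shape
        k, s, p = self.kernel, self.stride, self.pad
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.out_channels)
        self.grads["W"] = (dflat.T @ cols).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].reshape(self.out_channels, -1)).reshape(
            n, ho, wo, c, k, k
        )
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        self._cache = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with learned scale/shift and running moments."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        # buffers, not trained
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
            self._cache = (xhat, invstd.astype(np.float32))
            return (g * xhat + b).astype(np.float32)
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = None
        return (g * xhat + b).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        n, c, h, w = dout.shape
        m = n * h * w
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        g = self.params["gamma"][None, :, None, None]
        dx = (
            g
            * invstd[None, :, None, None]
            / m
            * (m * dout - dbeta[None, :, None, None] - xhat * dgamma[None, :, None, None])
        )
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._cache = (x > 0.0) if train else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._cache
        self._cache = None
        return dout * mask


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int, pad: int = 0) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.pad = pad

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        ho = conv_out_size(h, k, s, p)
        wo = conv_out_size(w, k, s, p)
        xp = _pad_hw(x, p, value=-np.inf)
        win = _windows(xp, k, s).reshape(n, c, ho, wo, k * k)
        arg = win.argmax(axis=-1)
        out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape)
        else:
            self._cache = None
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, x_shape = self._cache
        self._cache = None
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x_shape
        ho, wo = dout.shape[2], dout.shape[3]
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for idx in range(k * k):
            ki, kj = divmod(idx, k)
            contrib = np.where(arg == idx, dout, 0.0)
            dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += contrib
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class Linear(Layer):
    """Fully connected layer y = x W^T + b with He-normal init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_features)
        self.params["W"] = rng.normal(0.0, std, (out_features, in_features)).astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._cache = x if train else None
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        self.grads["W"] = dout.T @ x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]
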