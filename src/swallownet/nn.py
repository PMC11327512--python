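"""Minimal NumPy layer engine for the paired change-detection network.

Implements exactly the pieces the detector needs — 2-D convolution (im2col
with a 1x1 fast path), depthwise convolution, batch normalization, ReLU,
global average pooling, Adam, and binary cross-entropy on logits — with
hand-written backward passes. Compute is float32; losses and gradients of
the scalar head are accumulated in float64.

Layers cache their forward inputs, so each layer instance must be traversed
once per step (the model runs its shared encoder on a batch-stacked input
rather than calling it twice).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base class: forward caches what backward needs; params/grads parallel."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def param_items(self) -> Iterable[tuple[str, np.ndarray, np.ndarray]]:
        for name, p in self.params.items():
            yield name, p, self.grads[name]


def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


class Conv2d(Layer):
    """Standard convolution; bias-free (BatchNorm follows).

    1x1/stride-1 convolutions skip im2col and run as a single batched
    matmul over the flattened spatial axis.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int | tuple[int, int],
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kh, self.kw = _pair(kernel_size)
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * self.kh * self.kw
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.params["weight"] = rng.normal(
            0.0, scale, size=(out_channels, in_channels, self.kh, self.kw)
        ).astype(DTYPE)
        self.grads["weight"] = np.zeros_like(self.params["weight"])
        self._cache: tuple | None = None

    @property
    def _is_pointwise(self) -> bool:
        return self.kh == self.kw == 1 and self.stride == 1 and self.padding == 0

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        p, s = self.padding, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        windows = windows[:, :, ::s, ::s, :, :]
        b, c, ho, wo, _, _ = windows.shape
        cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(
            b, c * self.kh * self.kw, ho * wo
        )
        return np.ascontiguousarray(cols), (ho, wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        b, _, h, wdt = x.shape
        w = self.params["weight"].reshape(self.out_channels, -1)
        if self._is_pointwise:
            cols = x.reshape(b, self.in_channels, h * wdt)
            ho, wo = h, wdt
        else:
            cols, (ho, wo) = self._im2col(x)
        out = np.matmul(w[None], cols)
        self._cache = (x.shape, cols, (ho, wo))
        return out.reshape(b, self.out_channels, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols, (ho, wo) = self._cache
        b, _, h, wdt = x_shape
        grad = np.ascontiguousarray(grad, dtype=DTYPE)
        g = grad.reshape(b, self.out_channels, ho * wo)
        w = self.params["weight"].reshape(self.out_channels, -1)
        dw = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["weight"][...] = dw.reshape(self.params["weight"].shape)
        dcols = np.matmul(w.T[None], g)
        if self._is_pointwise:
            return dcols.reshape(x_shape)
        dcols = dcols.reshape(b, self.in_channels, self.kh, self.kw, ho, wo)
        p, s = self.padding, self.stride
        dxp = np.zeros((b, self.in_channels, h + 2 * p, wdt + 2 * p), dtype=DTYPE)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + wdt] if p else dxp


class DepthwiseConv2d(Layer):
    """Per-channel (groups == channels) convolution via strided tap sums."""

    def __init__(
        self,
        channels: int,
        kernel_size: int | tuple[int, int] = 3,
        stride: int = 1,
        padding: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.channels = channels
        self.kh, self.kw = _pair(kernel_size)
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (self.kh * self.kw))
        self.params["weight"] = rng.normal(
            0.0, scale, size=(channels, self.kh, self.kw)
        ).astype(DTYPE)
        self.grads["weight"] = np.zeros_like(self.params["weight"])
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        p, s = self.padding, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        b, c, hp, wp = xp.shape
        ho = (hp - self.kh) // s + 1
        wo = (wp - self.kw) // s + 1
        w = self.params["weight"]
        out = np.zeros((b, c, ho, wo), dtype=DTYPE)
        for i in range(self.kh):
            for j in range(self.kw):
                out += (
                    xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                    * w[None, :, i, j, None, None]
                )
        self._cache = (x.shape, xp)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, xp = self._cache
        b, c, h, wdt = x_shape
        grad = np.ascontiguousarray(grad, dtype=DTYPE)
        _, _, ho, wo = grad.shape
        p, s = self.padding, self.stride
        w = self.params["weight"]
        dw = np.empty_like(w)
        dxp = np.zeros_like(xp)
        for i in range(self.kh):
            for j in range(self.kw):
                tap = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                dw[:, i, j] = (grad * tap).sum(axis=(0, 2, 3))
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += (
                    grad * w[None, :, i, j, None, None]
                )
        self.grads["weight"][...] = dw
        return dxp[:, :, p : p + h, p : p + wdt] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.grads["gamma"] = np.zeros(channels, dtype=DTYPE)
        self.grads["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        axes = (0, 2, 3)
        if self.training:
            n = x.shape[0] * x.shape[2] * x.shape[3]
            mean = x.mean(axis=axes)
            sq_mean = np.einsum("bchw,bchw->c", x, x) / n
            var = np.maximum(sq_mean - mean * mean, 0.0)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = (
            self.params["gamma"][None, :, None, None] * xhat
            + self.params["beta"][None, :, None, None]
        )
        self._cache = (xhat, inv_std, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, x_shape = self._cache
        grad = np.ascontiguousarray(grad, dtype=DTYPE)
        axes = (0, 2, 3)
        self.grads["gamma"][...] = (grad * xhat).sum(axis=axes)
        self.grads["beta"][...] = grad.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None]
        if not self.training:
            return grad * g * inv_std[None, :, None, None]
        dxhat = grad * g
        term = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        )
        return term * inv_std[None, :, None, None]


class ReLU(Layer):
    """Rectifier applied in place: upstream layer outputs are not aliased."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        np.multiply(x, self._mask, out=x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        np.multiply(grad, self._mask, out=grad)
        return grad


class GlobalAvgPool(Layer):
    """Mean over the spatial axes, keeping (B, C, 1, 1)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3), keepdims=True, dtype=DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(grad / (h * w), self._shape).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            layer.training = self.training
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def param_items(self) -> Iterable[tuple[str, np.ndarray, np.ndarray]]:
        for i, layer in enumerate(self.layers):
            for name, p, g in layer.param_items():
                yield f"{i}.{name}", p, g


class InvertedResidual(Layer):
    """Expand (1x1) -> depthwise 3x3 -> project (1x1), residual when shapes allow."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        expand_ratio: int,
        stride: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        hidden = in_channels * expand_ratio
        self.use_residual = stride == 1 and in_channels == out_channels
        self.body = Sequential(
            [
                Conv2d(in_channels, hidden, 1, rng=rng),
                BatchNorm2d(hidden),
                ReLU(),
                DepthwiseConv2d(hidden, 3, stride=stride, padding=1, rng=rng),
                BatchNorm2d(hidden),
                ReLU(),
                Conv2d(hidden, out_channels, 1, rng=rng),
                BatchNorm2d(out_channels),
            ]
        )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.hidden = hidden
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.body.training = self.training
        out = self.body.forward(x)
        if self.use_residual:
            out = out + x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = self.body.backward(grad)
        if self.use_residual:
            dx = dx + grad
        return dx

    def param_items(self) -> Iterable[tuple[str, np.ndarray, np.ndarray]]:
        for name, p, g in self.body.param_items():
            yield f"body.{name}", p, g


class Adam:
    """Adam with conventional defaults; no weight decay."""

    def __init__(
        self,
        param_items: Sequence[tuple[str, np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.items = list(param_items)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in self.items]
        self.v = [np.zeros_like(p) for _, p, _ in self.items]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (_, p, g) in enumerate(self.items):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= (
                self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            ).astype(p.dtype)


def sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable mean BCE on logits; returns (loss, dloss/dlogits)."""
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))
    grad = (sigmoid(logits) - targets) / logits.size
    return float(loss.mean()), grad
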