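"""Layers of the CPU CNN engine: each knows its forward pass, backward pass
and trainable parameters.  Activations needed by the backward pass are cached
on the layer between the two calls (single-threaded training loop assumed).
"""
from __future__ import annotations

import numpy as np

from .functional import col2im, im2col

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "AvgPool2d",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Dropout",
    "Linear",
]


class Parameter:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return int(self.data.size)


class Module:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Conv2d(Module):
    """Cross-correlation with optional bias (the field's 'convolution')."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.kernel = kernel
        self.stride = stride
        self.pad = pad
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.w = Parameter(
            f"{name}.w", rng.normal(0.0, scale, (out_channels, fan_in)).astype(np.float32)
        )
        self.b = Parameter(f"{name}.b", np.zeros(out_channels)) if bias else None
        #: first-layer convs can skip the input gradient entirely
        self.needs_input_grad = True
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        oh = (h + 2 * self.pad - self.kernel) // self.stride + 1
        ow = (w + 2 * self.pad - self.kernel) // self.stride + 1
        cols = im2col(x, self.kernel, self.stride, self.pad)
        self._cols = cols  # kept for backward (training or saliency passes)
        self._x_shape = x.shape
        # one big 2-D GEMM instead of a batched 3-D product
        y = cols.reshape(-1, cols.shape[-1]) @ self.w.data.T
        if self.b is not None:
            y += self.b.data
        return y.reshape(n, oh * ow, self.out_channels).transpose(0, 2, 1).reshape(
            n, self.out_channels, oh, ow
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, oc, oh, ow = dy.shape
        k = self.kernel
        dyf = dy.reshape(n, oc, oh * ow).transpose(0, 2, 1).reshape(-1, oc)
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        self.w.grad += dyf.T @ cols2
        if self.b is not None:
            self.b.grad += dyf.sum(axis=0)
        self._cols = None
        if not self.needs_input_grad:
            return np.zeros(self._x_shape, dtype=dy.dtype)
        _, cin, h, w = self._x_shape
        # transposed-path unfold buffer: n * h * w * oc * k * k floats
        buffer_mb = n * h * w * oc * k * k * 4 / 2**20
        if self.stride == 1 and buffer_mb < 400:
            # transposed convolution: full correlation of dy with the
            # spatially flipped, channel-swapped kernel.  This keeps the GEMM
            # inner dimension at oc*k*k (fat), unlike the col2im route whose
            # inner dimension is only oc.
            w4 = self.w.data.reshape(oc, cin, k, k)
            w2 = w4[:, :, ::-1, ::-1].transpose(0, 2, 3, 1).reshape(oc * k * k, cin)
            cols_dy = im2col(dy, k, 1, k - 1 - self.pad)
            dx = cols_dy.reshape(-1, oc * k * k) @ w2
            return np.ascontiguousarray(
                dx.reshape(n, h, w, cin).transpose(0, 3, 1, 2)
            )
        dcols = dyf @ self.w.data
        return col2im(
            dcols.reshape(n, oh * ow, -1), self._x_shape, self.kernel, self.stride, self.pad
        )


class BatchNorm2d(Module):
    """Per-channel batch normalization with affine scale/shift.

    Training uses batch statistics and updates exponential running estimates;
    evaluation uses the running estimates.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, name: str = "bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        g = self.gamma.data[None, :, None, None]
        b = self.beta.data[None, :, None, None]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
            std = np.sqrt(var + self.eps).astype(np.float32)
            xhat = (x - mu[None, :, None, None]) / std[None, :, None, None]
            self._cache = (xhat, std, True)
            return (g * xhat + b).astype(np.float32)
        std = np.sqrt(self.running_var + self.eps).astype(np.float32)
        xhat = (x - self.running_mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, False)
        return (g * xhat + b).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, trained = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        if not trained:
            # eval mode: fixed affine transform, statistics carry no gradient
            return (dxhat / std[None, :, None, None]).astype(np.float32)
        n, c, h, w = dy.shape
        m = n * h * w
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - s1 / m - xhat * s2 / m) / std[None, :, None, None]
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool2d(Module):
    """Non-overlapping average pooling; odd trailing rows/cols are dropped,
    so the output side is floor(side / pool)."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.pool
        n, c, h, w = x.shape
        he, we = (h // p) * p, (w // p) * p
        self._x_shape = x.shape
        y = x[:, :, :he, :we].reshape(n, c, he // p, p, we // p, p).mean(axis=(3, 5))
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self.pool
        n, c, h, w = self._x_shape
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        up = np.repeat(np.repeat(dy, p, axis=2), p, axis=3) / (p * p)
        dx[:, :, : up.shape[2], : up.shape[3]] = up
        return dx


class MaxPool2d(Module):
    """Max pooling with stride and padding (used by the residual baseline stem)."""

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel = kernel
        self.stride = stride
        self.pad = pad

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        self._x_shape = x.shape
        xx = x.reshape(n * c, 1, h, w)
        if self.pad:
            xx = np.pad(xx, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2),
                        constant_values=-np.inf)
        cols = im2col(xx, self.kernel, self.stride, 0)  # (n*c, L, k*k)
        self._arg = cols.argmax(axis=2)
        self._l = cols.shape[1]
        oh = (h + 2 * self.pad - self.kernel) // self.stride + 1
        y = cols.max(axis=2).reshape(n, c, oh, -1)
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        k = self.kernel
        dcols = np.zeros((n * c, self._l, k * k), dtype=dy.dtype)
        flat = dy.reshape(n * c, self._l)
        idx0 = np.arange(n * c)[:, None]
        idx1 = np.arange(self._l)[None, :]
        dcols[idx0, idx1, self._arg] = flat
        dx = col2im(dcols, (n * c, 1, h + 2 * self.pad, w + 2 * self.pad), k, self.stride, 0)
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dx.reshape(n, c, h, w)


class GlobalAvgPool(Module):
    """Spatial mean -> (N, C). Identity in content when the side is already 1."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._x_shape).astype(dy.dtype)


class Flatten(Module):
    """Channel-major flatten of (N, C, H, W) to (N, C*H*W)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._x_shape)


class Dropout(Module):
    """Inverted dropout: active only in training mode.

    The random stream is the generator assigned to ``rng`` (set once per
    training run so results are reproducible from the run seed).
    """

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        name: str = "fc",
    ):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.w = Parameter(
            f"{name}.w", rng.normal(0.0, scale, (out_features, in_features)).astype(np.float32)
        )
        self.b = Parameter(f"{name}.b", np.zeros(out_features))

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._last_x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._last_x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.data
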