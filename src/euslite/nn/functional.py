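"""Array-level building blocks for the CPU CNN engine.

Convolutions are lowered to matrix multiplication through ``im2col`` so the
heavy lifting runs in BLAS.  Everything operates on float32 NCHW arrays.
"""
from __future__ import annotations

import numpy as np

__all__ = ["im2col", "col2im", "conv_out_side", "softmax", "cross_entropy"]


def conv_out_side(side: int, kernel: int, stride: int = 1, pad: int = 0) -> int:
    """Spatial side after a convolution: floor((side + 2*pad - kernel)/stride) + 1."""
    return (side + 2 * pad - kernel) // stride + 1


def im2col(x: np.ndarray, kernel: int, stride: int = 1, pad: int = 0) -> np.ndarray:
    """Unfold ``x`` of shape (N, C, H, W) into patches (N, L, C*k*k).

    L = out_h * out_w.  The inner ordering of each patch row is (C, k, k),
    matching a weight matrix flattened from (out_c, C, k, k).
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    oh = (h - kernel) // stride + 1
    ow = (w - kernel) // stride + 1
    sn, sc, sh, sw = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, oh, ow, kernel, kernel),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    )
    # (N, oh, ow, C, k, k) -> (N, L, C*k*k); this reshape copies.
    return np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, oh * ow, c * kernel * kernel
    )


def col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    kernel: int,
    stride: int = 1,
    pad: int = 0,
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter patch gradients back onto the image."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kernel) // stride + 1
    ow = (wp - kernel) // stride + 1
    d = dcols.reshape(n, oh, ow, c, kernel, kernel).transpose(0, 3, 1, 2, 4, 5)
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for i in range(kernel):
        for j in range(kernel):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits.

    ``labels`` are integer class indices of shape (N,).
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)
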