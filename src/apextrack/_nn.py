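"""Minimal NumPy neural-network primitives with explicit backward passes.

All tensors are ``float32`` in ``(N, C, H, W)`` layout.  Each primitive
returns its output together with whatever cache its backward pass needs;
nothing here owns parameters — the network (see :mod:`apextrack.unet`)
threads a flat parameter list through these functions so that parameter
collections stay plain lists of arrays and support element-wise algebra
(required by the blended relearning update).

Convolutions are evaluated as nine shifted channel-GEMMs rather than a
materialised im2col, which is both faster single-threaded and lighter on
memory at the feature-map sizes this package uses.
"""

from __future__ import annotations

import numpy as np

FLOAT = np.float32


def _pad_nhwc(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> contiguous (N, H+2, W+2, C) with 1-pixel zero pad."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    return np.ascontiguousarray(xp.transpose(0, 2, 3, 1))


def conv3x3(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
            want_cache: bool = True):
    """3x3 stride-1 same convolution (cross-correlation).

    weight: (C_out, C_in, 3, 3); bias: (C_out,).
    Returns (y, cache); cache is None when ``want_cache`` is False.
    """
    n, c, h, w = x.shape
    c_out = weight.shape[0]
    xt = _pad_nhwc(x)
    y = np.empty((n, h, w, c_out), dtype=FLOAT)
    y[:] = bias
    for ky in range(3):
        for kx in range(3):
            sl = xt[:, ky:ky + h, kx:kx + w, :].reshape(-1, c)
            y += sl.dot(weight[:, :, ky, kx].T).reshape(n, h, w, c_out)
    cache = (xt, x.shape) if want_cache else None
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2)), cache


def conv3x3_backward(dy: np.ndarray, cache, weight: np.ndarray):
    """Gradients of conv3x3 w.r.t. input, weight and bias."""
    xt, x_shape = cache
    n, c, h, w = x_shape
    c_out = weight.shape[0]
    dy_t = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, c_out)
    dweight = np.empty_like(weight)
    for ky in range(3):
        for kx in range(3):
            sl = xt[:, ky:ky + h, kx:kx + w, :].reshape(-1, c)
            dweight[:, :, ky, kx] = dy_t.T @ sl
    dbias = dy_t.sum(axis=0)
    # dx = same-conv of dy with channel-transposed, spatially flipped kernels
    w_flip = np.ascontiguousarray(weight.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
    dx, _ = conv3x3(dy, w_flip, np.zeros(c, dtype=FLOAT), want_cache=False)
    return dx, dweight, dbias


def relu(x: np.ndarray):
    y = np.maximum(x, 0)
    return y, (x > 0)


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def maxpool2(x: np.ndarray):
    """2x2 max pooling, stride 2. H and W must be even."""
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache) -> np.ndarray:
    idx, x_shape = cache
    n, c, h, w = x_shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx.reshape(x_shape))


def upsample2(x: np.ndarray) -> np.ndarray:
    """2x nearest-neighbour upsampling."""
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
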