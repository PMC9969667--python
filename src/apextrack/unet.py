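"""Simplified U-Net apex segmenter: architecture, init, forward, backward.

Four resolution levels (three 2x2 max-pool downsamplings, so a 640x480
input bottlenecks at 80x60), two 3x3 convolutions per level with ReLU,
nearest-neighbour upsampling followed by a 3x3 convolution, skip
connections by channel concatenation, and a sigmoid on the final
single-channel output.  Channel widths double per level from
``base_channels``.

Parameters live in a flat ``list[np.ndarray]`` ("ModelParameters") so two
structurally identical models support element-wise affine combination —
the property the online relearning update relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import FLOAT

#: number of downsampling steps (levels - 1); inputs must divide by 2**DOWN
DOWN = 3
DIVISOR = 2 ** DOWN


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``levels`` and ``kernel_size`` are fixed by the architecture (four
    resolution levels, 3x3 kernels everywhere); they are kept as fields so
    checkpoints are self-describing.
    """

    levels: int = 4
    base_channels: int = 16
    kernel_size: int = 3
    input_channels: int = 3
    output_channels: int = 1

    def __post_init__(self) -> None:
        if self.levels != 4:
            raise ValueError("architecture is fixed at 4 resolution levels")
        if self.kernel_size != 3:
            raise ValueError("architecture uses 3x3 kernels in every conv layer")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


def _conv_specs(config: NetworkConfig):
    """Ordered (name, c_in, c_out) for every convolution in the network."""
    c = config.base_channels
    ci = config.input_channels
    return [
        ("enc0a", ci, c), ("enc0b", c, c),
        ("enc1a", c, 2 * c), ("enc1b", 2 * c, 2 * c),
        ("enc2a", 2 * c, 4 * c), ("enc2b", 4 * c, 4 * c),
        ("bot_a", 4 * c, 8 * c), ("bot_b", 8 * c, 8 * c),
        ("up2", 8 * c, 4 * c), ("dec2a", 8 * c, 4 * c), ("dec2b", 4 * c, 4 * c),
        ("up1", 4 * c, 2 * c), ("dec1a", 4 * c, 2 * c), ("dec1b", 2 * c, 2 * c),
        ("up0", 2 * c, c), ("dec0a", 2 * c, c), ("dec0b", c, c),
        ("out", c, config.output_channels),
    ]


def init_params(config: NetworkConfig, seed: int) -> list[np.ndarray]:
    """He-normal weight init for the ReLU convs; the output conv gets a
    negative bias so the initial foreground probability is low, which keeps
    the early Dice gradients pointing at the (sparse) target instead of at
    the background."""
    rng = np.random.default_rng(seed)
    params: list[np.ndarray] = []
    for name, c_in, c_out in _conv_specs(config):
        fan_in = c_in * 9
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(c_out, c_in, 3, 3)).astype(FLOAT)
        b = np.zeros(c_out, dtype=FLOAT)
        if name == "out":
            b[:] = -2.0
        params.extend([w, b])
    return params


def param_shapes(config: NetworkConfig):
    shapes = []
    for _, c_in, c_out in _conv_specs(config):
        shapes.extend([(c_out, c_in, 3, 3), (c_out,)])
    return shapes


def check_input(x: np.ndarray) -> None:
    if x.ndim != 4:
        raise ValueError("expected (N, C, H, W) input")
    _, _, h, w = x.shape
    if h % DIVISOR or w % DIVISOR:
        raise ValueError(
            f"input height and width must be divisible by {DIVISOR} "
            f"(3 halvings); got {h}x{w}"
        )


def forward(params: list[np.ndarray], x: np.ndarray, want_cache: bool = True):
    """Run the network.

    Returns ``(prob, info)`` where ``prob`` is the (N, 1, H, W) sigmoid
    output and ``info`` carries the backward cache (or only the bottleneck
    shape when ``want_cache`` is False).
    """
    check_input(x)
    w = {i: params[2 * i] for i in range(18)}
    b = {i: params[2 * i + 1] for i in range(18)}
    cc = []          # conv caches, in conv order
    rm = []          # relu masks, in relu order
    pc = []          # pool caches

    def conv_relu(i, h):
        y, cache = _nn.conv3x3(h, w[i], b[i], want_cache)
        cc.append(cache)
        y, mask = _nn.relu(y)
        rm.append(mask if want_cache else None)
        return y

    h = x.astype(FLOAT) if x.dtype != FLOAT else x
    s0 = conv_relu(1, conv_relu(0, h))
    h, c = _nn.maxpool2(s0); pc.append(c)
    s1 = conv_relu(3, conv_relu(2, h))
    h, c = _nn.maxpool2(s1); pc.append(c)
    s2 = conv_relu(5, conv_relu(4, h))
    h, c = _nn.maxpool2(s2); pc.append(c)
    h = conv_relu(7, conv_relu(6, h))
    bottleneck_shape = h.shape

    h = conv_relu(8, _nn.upsample2(h))
    h = conv_relu(10, conv_relu(9, np.concatenate([s2, h], axis=1)))
    h = conv_relu(11, _nn.upsample2(h))
    h = conv_relu(13, conv_relu(12, np.concatenate([s1, h], axis=1)))
    h = conv_relu(14, _nn.upsample2(h))
    h = conv_relu(16, conv_relu(15, np.concatenate([s0, h], axis=1)))
    logits, cache = _nn.conv3x3(h, w[17], b[17], want_cache)
    cc.append(cache)
    prob = _nn.sigmoid(logits)

    if not want_cache:
        return prob, {"bottleneck_shape": bottleneck_shape}
    skip_ch = (s0.shape[1], s1.shape[1], s2.shape[1])
    return prob, {
        "bottleneck_shape": bottleneck_shape,
        "conv_caches": cc,
        "relu_masks": rm,
        "pool_caches": pc,
        "skip_channels": skip_ch,
        "prob": prob,
    }


def backward(params: list[np.ndarray], info, dprob: np.ndarray) -> list[np.ndarray]:
    """Gradient of a scalar loss w.r.t. every parameter, given dL/dprob."""
    w = {i: params[2 * i] for i in range(18)}
    cc = info["conv_caches"]
    rm = info["relu_masks"]
    pc = info["pool_caches"]
    c0, c1, c2 = info["skip_channels"]
    prob = info["prob"]

    grads = [None] * 36

    def conv_back(i, cache_idx, dy):
        dx, dw, db = _nn.conv3x3_backward(dy, cc[cache_idx], w[i])
        grads[2 * i] = dw
        grads[2 * i + 1] = db
        return dx

    def conv_relu_back(i, cache_idx, dy):
        return conv_back(i, cache_idx, _nn.relu_backward(dy, rm[cache_idx]))

    dlogits = (dprob * prob * (1.0 - prob)).astype(FLOAT)
    d = conv_back(17, 17, dlogits)

    d = conv_relu_back(15, 15, conv_relu_back(16, 16, d))
    ds0 = d[:, :c0]
    d = _nn.upsample2_backward(conv_relu_back(14, 14, d[:, c0:]))
    d = conv_relu_back(12, 12, conv_relu_back(13, 13, d))
    ds1 = d[:, :c1]
    d = _nn.upsample2_backward(conv_relu_back(11, 11, d[:, c1:]))
    d = conv_relu_back(9, 9, conv_relu_back(10, 10, d))
    ds2 = d[:, :c2]
    d = _nn.upsample2_backward(conv_relu_back(8, 8, d[:, c2:]))

    d = conv_relu_back(6, 6, conv_relu_back(7, 7, d))
    d = _nn.maxpool2_backward(d, pc[2]) + ds2
    d = conv_relu_back(4, 4, conv_relu_back(5, 5, d))
    d = _nn.maxpool2_backward(d, pc[1]) + ds1
    d = conv_relu_back(2, 2, conv_relu_back(3, 3, d))
    d = _nn.maxpool2_backward(d, pc[0]) + ds0
    conv_relu_back(0, 0, conv_relu_back(1, 1, d))
    return grads
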