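"""Feature connection module: gated recombination of fused skip and decoder.

The cross-fused encoder output O_i is aligned to the decoder feature D_i
(nearest-neighbour upsampling plus a convolution when resolutions differ),
both are globally average-pooled per channel, passed through one linear
layer each, and the sum of the two linear outputs is squashed into a
per-channel sigmoid gate.  The gate rescales O_i channel-wise (an
SE-style reading of the recombination) and the gated O_i is concatenated
with D_i for the decoder block.  ``mode="add"`` selects the rejected
alternative reading in which the gate is added to O_i instead.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor
from .nn import functional as F

__all__ = ["FeatureConnection"]


class FeatureConnection(Module):
    """One feature-connection block at a given channel width."""

    def __init__(self, channels: int, rng: np.random.Generator, mode: str = "gate"):
        super().__init__()
        if mode not in ("gate", "add"):
            raise ValueError(f"unknown fc mode {mode!r}; valid: gate, add")
        self.mode = mode
        self.channels = channels
        self.align_conv = Conv2d(channels, channels, 3, rng)
        self.linear_o = Linear(channels, channels, rng)
        self.linear_d = Linear(channels, channels, rng)

    def align(self, o_i: Tensor, target: Tensor) -> Tensor:
        """Upsample + convolve O_i to the spatial grid of ``target``."""
        _, c, h, w = o_i.shape
        _, _, th, tw = target.shape
        if c != self.channels:
            raise ValueError(f"align: expected {self.channels} channels, got {c}")
        if th % h or tw % w or (th // h) != (tw // w):
            raise ValueError(
                f"align: target {(th, tw)} is not an integer multiple of {(h, w)}"
            )
        factor = th // h
        if factor > 1:
            o_i = F.upsample_nearest(o_i, factor)
        return self.align_conv(o_i)

    def gate(self, o_i: Tensor, d_i: Tensor) -> Tensor:
        """Per-channel sigmoid gate from the two pooled linear branches."""
        pooled_o = o_i.mean(axis=(2, 3))  # global average pooling, (N, C)
        pooled_d = d_i.mean(axis=(2, 3))
        return (self.linear_o(pooled_o) + self.linear_d(pooled_d)).sigmoid()

    def connect(self, o_i: Tensor, d_i: Tensor) -> Tensor:
        """Gated recombination; output has channels(O_i) + channels(D_i)."""
        if o_i.shape[2:] != d_i.shape[2:]:
            raise ValueError(
                f"connect: O_i spatial {o_i.shape[2:]} != D_i {d_i.shape[2:]}; "
                "align O_i first"
            )
        g = self.gate(o_i, d_i).reshape(o_i.shape[0], o_i.shape[1], 1, 1)
        if self.mode == "gate":
            gated = o_i * g
        else:
            gated = o_i + g
        from .nn import concatenate

        return concatenate([gated, d_i], axis=1)

    def forward(self, o_i: Tensor, d_i: Tensor) -> Tensor:
        return self.connect(self.align(o_i, d_i), d_i)
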