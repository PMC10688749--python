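"""Tensor low-rank context module.

Per encoder stage, contextual information is summarised as 3L rank-1
vectors: L along each of the height, width and channel axes.  Each vector
is produced by a feature generator consisting of global average pooling
along the collapsed axes, a single-channel 1-D convolution, and a sigmoid
that rescales the result into [0, 1].  Distinct generators carry distinct
parameters so their outputs reflect distinct context fragments.  The
vectors are never expanded into full outer-product tensors; they are
consumed additively by the channel cross-fusion tokens, keeping the cost
O(L * (H + W + C)) per stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv1d, Module, Tensor, concatenate

DIRECTIONS = ("height", "width", "channel")

#: axes of a (N, C, H, W) batch collapsed by the pooling, per direction
_COLLAPSED = {"height": (1, 3), "width": (1, 2), "channel": (2, 3)}


@dataclass
class RankOneContext:
    """The 3L rank-1 context vectors of one encoder stage.

    ``vectors[d]`` is an (L, axis_len) array with entries in [0, 1];
    ``axis_len`` is the size of the kept axis of the source feature map.
    """

    stage: int
    vectors: dict[str, np.ndarray]

    @property
    def L(self) -> int:
        return next(iter(self.vectors.values())).shape[0]

    @property
    def n_vectors(self) -> int:
        return sum(v.shape[0] for v in self.vectors.values())


def direction_pool(feature, direction: str):
    """Global average pooling keeping one axis of a (C, H, W) feature map.

    Entry ``k`` of the result is the mean of every element whose index along
    the kept axis equals ``k``.  Accepts a batched (N, C, H, W) Tensor (used
    inside the network) or an unbatched (C, H, W) array, returning the same
    kind it was given.
    """
    if direction not in _COLLAPSED:
        raise ValueError(
            f"unknown direction {direction!r}; valid: {', '.join(DIRECTIONS)}"
        )
    if isinstance(feature, Tensor):
        if feature.ndim != 4:
            raise ValueError("Tensor input must be batched (N, C, H, W)")
        return feature.mean(axis=_COLLAPSED[direction])
    arr = np.asarray(feature)
    if arr.ndim != 3:
        raise ValueError("array input must be (C, H, W)")
    pooled = Tensor(arr[None]).mean(axis=_COLLAPSED[direction])
    return pooled.data[0]


class ContextGenerator(Module):
    """L feature generators per direction for one encoder stage."""

    def __init__(self, L: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if L < 1:
            raise ValueError("L must be >= 1")
        self.L = L
        for d in DIRECTIONS:
            for ell in range(L):
                self.register_module(f"{d}{ell}", Conv1d(kernel, rng))

    def _generators(self, direction: str) -> list[Conv1d]:
        return [self._modules[f"{direction}{ell}"] for ell in range(self.L)]

    def forward(self, feature: Tensor) -> dict[str, Tensor]:
        """Batched context: direction -> (N, L, axis_len) Tensor in (0, 1)."""
        out: dict[str, Tensor] = {}
        for d in DIRECTIONS:
            pooled = direction_pool(feature, d)  # (N, axis_len)
            vecs = [
                gen(pooled).sigmoid().reshape(pooled.shape[0], 1, pooled.shape[1])
                for gen in self._generators(d)
            ]
            out[d] = vecs[0] if len(vecs) == 1 else concatenate(vecs, axis=1)
        return out


def generate_context(
    feature, L: int, params: ContextGenerator | None = None, *,
    stage: int = 1, kernel: int = 3, rng: np.random.Generator | None = None,
) -> RankOneContext:
    """Produce the 3L rank-1 context vectors of a single (C, H, W) feature map.

    ``params`` supplies the generator weights; if omitted, fresh generators
    are initialised from ``rng`` (seed 0 by default).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if params is None:
        params = ContextGenerator(L, kernel, rng or np.random.default_rng(0))
    elif params.L != L:
        raise ValueError(f"params hold L={params.L} generators, requested {L}")
    arr = np.asarray(feature, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("feature must be (C, H, W)")
    ctx = params(Tensor(arr[None]))
    return RankOneContext(
        stage=stage, vectors={d: v.data[0] for d, v in ctx.items()}
    )
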