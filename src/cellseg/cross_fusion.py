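"""Channel cross-fusion module.

The per-stage encoder features are re-expressed as token sequences by
multi-scale patch embedding (patch edges P_s / 2^(i-1), so every stage
yields the same token count), concatenated across the four scales, and
fused by channel-wise cross attention: queries come from one stage, keys
and values from the all-scale concatenation, and the score matrix lives on
the embedding (channel) axis rather than the token axis.  Head outputs are
arithmetically averaged and a two-layer perceptron recombines queries and
attended context per direction; the three direction terms are summed and
un-patched back to a spatial feature map O_i that replaces the plain skip.

Because the concatenated sequence carries 4n tokens while a query stage
carries n, the channel score product sums the keys' four scale blocks
(S = Q^T sum_i K_i, an embed_dim x embed_dim matrix) and the attended
values are folded back from 4n to n tokens by averaging the four scale
blocks.  Scores are instance-normalised before the softmax, which plays
the role of the usual 1/sqrt(d_k) temperature.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .low_rank import DIRECTIONS
from .nn import DTYPE, Linear, Module, Tensor, concatenate, he_uniform

__all__ = [
    "concat_scales",
    "cross_attention",
    "multi_head_average",
    "fuse_stage",
    "ChannelCrossFusion",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concat_scales(token_seqs: list, axis: int = -2) -> Tensor:
    """Concatenate per-stage token sequences along the token axis.

    Input sequences are (..., n_tokens, embed_dim); the output carries the
    tokens of all scales in stage order.
    """
    seqs = [_as_tensor(t) for t in token_seqs]
    dims = {s.shape[-1] for s in seqs}
    if len(dims) != 1:
        raise ValueError(f"embed_dim mismatch across scales: {sorted(dims)}")
    return concatenate(seqs, axis=axis if axis >= 0 else seqs[0].ndim + axis)


def _instance_norm(s: Tensor, eps: float = 1e-5) -> Tensor:
    axes = tuple(range(s.ndim - 2, s.ndim))
    mu = s.mean(axis=axes, keepdims=True)
    var = ((s - mu) ** 2).mean(axis=axes, keepdims=True)
    return (s - mu) / ((var + eps) ** 0.5)


def cross_attention(
    t_di, t_dsum, w_q, w_k, w_v, *, return_weights: bool = False
):
    """Channel-wise cross attention of one head.

    ``t_di`` (n, E) or (N, n, E) queries one stage; ``t_dsum`` (m, E) with
    m a multiple of n carries the concatenated scales supplying keys and
    values.  Scores are the embed x embed channel product of the queries
    with the scale-summed keys, instance-normalised and softmaxed over the
    key-channel axis; attended values are averaged back over the scale
    blocks to the query layout.
    """
    t_di, t_dsum = _as_tensor(t_di), _as_tensor(t_dsum)
    w_q, w_k, w_v = _as_tensor(w_q), _as_tensor(w_k), _as_tensor(w_v)
    if t_di.shape[-1] != t_dsum.shape[-1]:
        raise ValueError(
            f"embed_dim mismatch: queries {t_di.shape[-1]} vs keys {t_dsum.shape[-1]}"
        )
    e = t_di.shape[-1]
    for name, w in (("W_Q", w_q), ("W_K", w_k), ("W_V", w_v)):
        if w.shape[-2] != e:
            raise ValueError(f"{name} rows {w.shape[-2]} != embed_dim {e}")
    n = t_di.shape[-2]
    m = t_dsum.shape[-2]
    if m % n:
        raise ValueError(f"key tokens {m} not a multiple of query tokens {n}")
    scales = m // n
    batched = t_di.ndim == 3
    if not batched:
        t_di = t_di.reshape(1, n, e)
        t_dsum = t_dsum.reshape(1, m, e)
    nb = t_di.shape[0]

    q = t_di @ w_q                           # (N, n, E)
    k = t_dsum @ w_k                         # (N, m, E)
    v = t_dsum @ w_v
    k_sum = k.reshape(nb, scales, n, e).sum(axis=1)          # (N, n, E)
    scores = q.swapaxes(-1, -2) @ k_sum                      # (N, E, E)
    weights = _instance_norm(scores).softmax(axis=-1)
    attended = v @ weights.swapaxes(-1, -2)                  # (N, m, E)
    ca = attended.reshape(nb, scales, n, e).mean(axis=1)     # (N, n, E)
    if not batched:
        ca = ca.reshape(n, e)
        weights = weights.reshape(e, e)
    if return_weights:
        return ca, weights
    return ca


def multi_head_average(heads: list) -> Tensor:
    """Elementwise arithmetic mean of the N head outputs."""
    if not heads:
        raise ValueError("multi_head_average requires at least one head")
    heads = [_as_tensor(h) for h in heads]
    shapes = {h.shape for h in heads}
    if len(shapes) != 1:
        raise ValueError(f"head shape mismatch: {sorted(shapes)}")
    out = heads[0]
    for h in heads[1:]:
        out = out + h
    return out * (1.0 / len(heads))


def fuse_stage(q_parts: dict, nca_parts: dict, perceptron) -> Tensor:
    """O_i tokens = sum over directions of NCA + LP(Q + NCA)."""
    if set(q_parts) != set(nca_parts):
        raise ValueError("query and attention parts must cover the same directions")
    shapes = {_as_tensor(v).shape for v in nca_parts.values()}
    if len(shapes) != 1:
        raise ValueError(f"NCA shape mismatch across directions: {sorted(shapes)}")
    out = None
    for d in q_parts:
        q, nca = _as_tensor(q_parts[d]), _as_tensor(nca_parts[d])
        term = nca + perceptron(q + nca)
        out = term if out is None else out + term
    return out


class _Perceptron(Module):
    """Two-layer GELU perceptron with hidden width 4x embed_dim."""

    def __init__(self, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(embed_dim, 4 * embed_dim, rng)
        self.fc2 = Linear(4 * embed_dim, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class ChannelCrossFusion(Module):
    """Full cross-fusion block over all encoder stages.

    Owns the per-stage patch embed/un-embed projections, the per-direction
    per-head Q/K/V weights (shared across stages), the shared fusion
    perceptron and, when rank-1 context is supplied, the per-direction
    context embedding vectors.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.depth = config.depth
        e = config.embed_dim
        for i in range(1, self.depth + 1):
            p = config.patch_size // 2 ** (i - 1)
            c = config.stage_channels(i)
            self.register_module(f"embed{i}", Linear(c * p * p, e, rng))
            self.register_module(f"unembed{i}", Linear(e, c * p * p, rng))
        for d in DIRECTIONS:
            for h in range(config.heads_N):
                for role in ("q", "k", "v"):
                    name = f"w_{role}_{d}_{h}"
                    setattr(
                        self, name, Tensor(he_uniform(rng, (e, e), e), requires_grad=True)
                    )
        self.perceptron = _Perceptron(e, rng)
        if config.uses_lr:
            for d in DIRECTIONS:
                setattr(
                    self,
                    f"ctx_{d}",
                    Tensor(he_uniform(rng, (config.rank_L, e), config.rank_L), requires_grad=True),
                )

    # ------------------------------------------------------------- patches
    def _patch_geometry(self, stage: int, h: int, w: int) -> tuple[int, int, int]:
        p = self.config.patch_size // 2 ** (stage - 1)
        if p < 1:
            raise ValueError(f"patch size vanishes at stage {stage}")
        if h % p or w % p:
            raise ValueError(
                f"stage {stage} spatial size {(h, w)} not divisible by patch edge {p}"
            )
        return p, h // p, w // p

    def embed_patches(self, feature: Tensor, stage: int) -> Tensor:
        """(N, C, H, W) -> (N, n_tokens, embed_dim) via learned projection
        of flattened patches; n_tokens = (H/p)(W/p) with p = P_s/2^(i-1)."""
        feature = _as_tensor(feature)
        nb, c, h, w = feature.shape
        p, gh, gw = self._patch_geometry(stage, h, w)
        patches = (
            feature.reshape(nb, c, gh, p, gw, p)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(nb, gh * gw, c * p * p)
        )
        return self._modules[f"embed{stage}"](patches)

    def unpatch(self, tokens: Tensor, stage: int, h: int, w: int) -> Tensor:
        """Inverse of :meth:`embed_patches` through the learned un-embedding."""
        nb = tokens.shape[0]
        c = self.config.stage_channels(stage)
        p, gh, gw = self._patch_geometry(stage, h, w)
        flat = self._modules[f"unembed{stage}"](tokens)
        return (
            flat.reshape(nb, gh, gw, c, p, p)
            .transpose(0, 3, 1, 4, 2, 5)
            .reshape(nb, c, h, w)
        )

    # -------------------------------------------------------------- context
    def _context_tokens(
        self, ctx: Tensor, direction: str, stage: int, h: int, w: int
    ) -> Tensor:
        """Project one stage's rank-1 vectors (N, L, axis_len) onto tokens.

        Each vector is averaged over the token's span along its axis and
        scaled into the shared embedding by a learned per-vector direction
        embedding — an additive rank-1 projection, linear in L.
        """
        nb, L = ctx.shape[0], ctx.shape[1]
        p, gh, gw = self._patch_geometry(stage, h, w)
        w_ctx = getattr(self, f"ctx_{direction}")  # (L, E)
        if direction == "channel":
            per_image = ctx.mean(axis=2).reshape(nb, 1, L)       # (N, 1, L)
            return per_image @ w_ctx                             # (N, 1, E) broadcasts
        if direction == "height":
            per_row = ctx.reshape(nb, L, gh, p).mean(axis=3)     # (N, L, gh)
            grid = per_row.reshape(nb, L, gh, 1) * Tensor(
                np.ones((1, 1, 1, gw), dtype=DTYPE)
            )
        else:  # width
            per_col = ctx.reshape(nb, L, gw, p).mean(axis=3)     # (N, L, gw)
            grid = per_col.reshape(nb, L, 1, gw) * Tensor(
                np.ones((1, 1, gh, 1), dtype=DTYPE)
            )
        tokens = grid.reshape(nb, L, gh * gw).swapaxes(1, 2)     # (N, n, L)
        return tokens @ w_ctx                                    # (N, n, E)

    # -------------------------------------------------------------- forward
    def forward(
        self, stage_features: list[Tensor], contexts: list[dict] | None = None
    ) -> list[Tensor]:
        """Fuse the encoder stages; returns the per-stage O_i feature maps.

        ``contexts`` (optional) is the per-stage output of the low-rank
        context generators, direction -> (N, L, axis_len).
        """
        if len(stage_features) != self.depth:
            raise ValueError(
                f"expected {self.depth} stage features, got {len(stage_features)}"
            )
        sizes = [(f.shape[2], f.shape[3]) for f in stage_features]
        base = [
            self.embed_patches(f, i + 1) for i, f in enumerate(stage_features)
        ]
        counts = {t.shape[1] for t in base}
        if len(counts) != 1:
            raise ValueError(f"token counts differ across stages: {sorted(counts)}")

        tokens: dict[str, list[Tensor]] = {}
        for d in DIRECTIONS:
            if contexts is not None:
                tokens[d] = [
                    base[i]
                    + self._context_tokens(contexts[i][d], d, i + 1, *sizes[i])
                    for i in range(self.depth)
                ]
            else:
                tokens[d] = base
        t_sum = {d: concat_scales(tokens[d]) for d in DIRECTIONS}

        # keys/values depend only on the concatenated sequence: hoist them
        # out of the stage loop (one K, V and scale-summed K per d, head)
        n_heads = self.config.heads_N
        nb = t_sum[DIRECTIONS[0]].shape[0]
        n_tok = base[0].shape[1]
        e = self.config.embed_dim
        kv: dict[tuple[str, int], tuple[Tensor, Tensor]] = {}
        for d in DIRECTIONS:
            for hh in range(n_heads):
                k = t_sum[d] @ getattr(self, f"w_k_{d}_{hh}")
                v = t_sum[d] @ getattr(self, f"w_v_{d}_{hh}")
                k_sum = k.reshape(nb, self.depth, n_tok, e).sum(axis=1)
                kv[(d, hh)] = (k_sum, v)

        outputs: list[Tensor] = []
        for i in range(self.depth):
            q_parts: dict[str, Tensor] = {}
            nca_parts: dict[str, Tensor] = {}
            for d in DIRECTIONS:
                heads = []
                q_heads = []
                for hh in range(n_heads):
                    k_sum, v = kv[(d, hh)]
                    q = tokens[d][i] @ getattr(self, f"w_q_{d}_{hh}")
                    scores = q.swapaxes(-1, -2) @ k_sum
                    weights = _instance_norm(scores).softmax(axis=-1)
                    attended = v @ weights.swapaxes(-1, -2)
                    heads.append(
                        attended.reshape(nb, self.depth, n_tok, e).mean(axis=1)
                    )
                    q_heads.append(q)
                nca_parts[d] = multi_head_average(heads)
                q_parts[d] = multi_head_average(q_heads)
            o_tok = fuse_stage(q_parts, nca_parts, self.perceptron)
            outputs.append(self.unpatch(o_tok, i + 1, *sizes[i]))
        return outputs
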