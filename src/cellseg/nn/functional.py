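"""Structured network operations with hand-written backward passes.

Convolution, pooling and batch normalisation are the hot path of the
network, so instead of composing them from scalar primitives each gets a
dedicated vectorised forward/backward pair (im2col matmul convolutions,
reshape-trick pooling).  All operate on NCHW layouts.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv1d",
    "conv_transpose2d",
    "max_pool2d",
    "batch_norm2d",
    "upsample_nearest",
]


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Single-channel, stride-1, same-padded 1-D cross-correlation.

    ``x`` is (N, L) — a batch of pooled direction vectors — ``weight`` (k,)
    with odd k, ``bias`` a scalar (1,).
    """
    n, length = x.shape
    (k,) = weight.shape
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad)))
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(xp, (n, length, k), (s[0], s[1], s[1]))
    out = cols @ weight.data
    if bias is not None:
        out = out + bias.data

    def grad_x(g):
        # correlation adjoint = convolution with the flipped kernel
        gp = np.pad(g, ((0, 0), (pad, pad)))
        gs = gp.strides
        gcols = np.lib.stride_tricks.as_strided(gp, (n, length, k), (gs[0], gs[1], gs[1]))
        return gcols @ weight.data[::-1].copy()

    def grad_w(g):
        return np.einsum("nl,nlk->k", g, cols, optimize=True)

    parents = [x, weight]
    fns = [grad_x, grad_w]
    if bias is not None:
        parents.append(bias)
        fns.append(lambda g: np.atleast_1d(g.sum()))
    return Tensor._make(out, tuple(parents), tuple(fns))


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, H*W) patches for a stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh * kw, h, w), dtype=x.dtype)
    for a in range(kh):  # slice copies beat a strided gather here
        for b in range(kw):
            cols[:, :, a * kw + b] = xp[:, :, a : a + h, b : b + w]
    return cols.reshape(n, c * kh * kw, h * w)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1, same-padded 2-D cross-correlation.

    ``x`` is (N,C,H,W), ``weight`` (O,C,kh,kw) with odd kernel edges, ``bias``
    (O,).  Same padding keeps encoder/decoder features aligned without crops.
    """
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    pad = kh // 2
    cols = _im2col(x.data, kh, kw, pad)  # (N, CK, HW)
    w2 = weight.data.reshape(o, c * kh * kw)
    out = np.matmul(w2, cols).reshape(n, o, h, w)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)

    def grad_x(g):
        g2 = g.reshape(n, o, h * w)
        dcols = np.matmul(w2.T, g2).reshape(n, c, kh, kw, h, w)
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=g.dtype)
        for a in range(kh):
            for b in range(kw):
                dxp[:, :, a : a + h, b : b + w] += dcols[:, :, a, b]
        return dxp[:, :, pad : pad + h, pad : pad + w]

    def grad_w(g):
        g2 = g.reshape(n, o, h * w)
        dw = np.einsum("nop,nkp->ok", g2, cols, optimize=True)
        return dw.reshape(weight.shape)

    parents = [x, weight]
    fns = [grad_x, grad_w]
    if bias is not None:
        parents.append(bias)
        fns.append(lambda g: g.sum(axis=(0, 2, 3)))
    return Tensor._make(out, tuple(parents), tuple(fns))


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2x2, stride-2 transposed convolution (the U-Net up-conv).

    ``x`` (N,C,H,W), ``weight`` (C,O,2,2) -> (N,O,2H,2W).  With stride equal
    to the kernel edge the output windows never overlap, so the op reduces to
    an einsum and an interleaving reshape.
    """
    n, c, h, w = x.shape
    ci, o, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"conv_transpose2d: input has {c} channels, weight expects {ci}")
    out = np.einsum("nchw,coab->nohawb", x.data, weight.data, optimize=True)
    out = out.reshape(n, o, h * kh, w * kw)
    if bias is not None:
        out = out + bias.data.reshape(1, o, 1, 1)

    def grad_x(g):
        g6 = g.reshape(n, o, h, kh, w, kw)
        return np.einsum("nohawb,coab->nchw", g6, weight.data, optimize=True)

    def grad_w(g):
        g6 = g.reshape(n, o, h, kh, w, kw)
        return np.einsum("nchw,nohawb->coab", x.data, g6, optimize=True)

    parents = [x, weight]
    fns = [grad_x, grad_w]
    if bias is not None:
        parents.append(bias)
        fns.append(lambda g: g.sum(axis=(0, 2, 3)))
    return Tensor._make(out, tuple(parents), tuple(fns))


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling; ties route the gradient to the
    first maximal element of each window."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"max_pool2d: spatial dims {(h, w)} not divisible by {k}")
    ho, wo = h // k, w // k
    win = x.data.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, ho, wo, k * k
    )
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def grad_fn(g):
        dwin = np.zeros((n, c, ho, wo, k * k), dtype=g.dtype)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        return (
            dwin.reshape(n, c, ho, wo, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    return Tensor._make(out, (x,), (grad_fn,))


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour spatial upsampling by an integer factor."""
    n, c, h, w = x.shape
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def grad_fn(g):
        return g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))

    return Tensor._make(out, (x,), (grad_fn,))


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over (N,H,W).

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running buffers are used and the op
    is a plain affine map.
    """
    n, c, h, w = x.shape
    g4 = gamma.data.reshape(1, c, 1, 1)
    b4 = beta.data.reshape(1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
        out = g4 * xhat + b4
        m = n * h * w

        def grad_x(g):
            gg = g * g4
            mean_g = gg.mean(axis=(0, 2, 3), keepdims=True)
            mean_gx = (gg * xhat).mean(axis=(0, 2, 3), keepdims=True)
            return inv.reshape(1, c, 1, 1) * (gg - mean_g - xhat * mean_gx)

        def grad_gamma(g):
            return (g * xhat).sum(axis=(0, 2, 3))

    else:
        inv = 1.0 / np.sqrt(running_var + eps)
        xhat = (x.data - running_mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
        out = g4 * xhat + b4

        def grad_x(g):
            return g * (g4 * inv.reshape(1, c, 1, 1))

        def grad_gamma(g):
            return (g * xhat).sum(axis=(0, 2, 3))

    return Tensor._make(
        out,
        (x, gamma, beta),
        (grad_x, grad_gamma, lambda g: g.sum(axis=(0, 2, 3))),
    )
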