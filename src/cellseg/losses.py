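"""Training losses: weighted cross-entropy, soft Dice, and their alpha blend.

The weighted cross-entropy multiplies the foreground (positive) term by
beta to counter the heavy class imbalance of cell images, where foreground
pixels are far outnumbered by background:

    WCE(p, p_hat) = -mean( beta * p * log(p_hat) + (1 - p) * log(1 - p_hat) )

The Dice loss is the soft (probability-valued) complement of the Dice
coefficient 2|X n Y| / (|X| + |Y|), smoothed by epsilon, and the training
loss blends the two:  L = alpha * WCE + (1 - alpha) * Dice.

All three accept either autodiff Tensors (training path) or plain arrays;
they return whatever kind they were given.
"""

from __future__ import annotations

import numpy as np

from .config import LossConfig
from .nn import Tensor

__all__ = ["weighted_cross_entropy", "dice_loss", "combined_loss"]


def _prepare(p_hat, p):
    wrapped = isinstance(p_hat, Tensor) or isinstance(p, Tensor)
    p_hat = p_hat if isinstance(p_hat, Tensor) else Tensor(np.asarray(p_hat, dtype=np.float64))
    p = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=p_hat.dtype))
    if p_hat.shape != p.shape:
        raise ValueError(f"shape mismatch: prediction {p_hat.shape} vs target {p.shape}")
    return p_hat, p, wrapped


def weighted_cross_entropy(p_hat, p, beta: float = 1.0, epsilon: float = 1e-6):
    """Pixel-averaged WCE; predictions are clamped to [eps, 1-eps]."""
    p_hat, p, wrapped = _prepare(p_hat, p)
    q = p_hat.clip(epsilon, 1.0 - epsilon)
    loss = -(beta * p * q.log() + (1.0 - p) * (1.0 - q).log()).mean()
    return loss if wrapped else loss.item()


def dice_loss(p_hat, p, epsilon: float = 1e-6):
    """1 - (2 sum(p_hat*p) + eps) / (sum(p_hat) + sum(p) + eps)."""
    p_hat, p, wrapped = _prepare(p_hat, p)
    inter = (p_hat * p).sum()
    denom = p_hat.sum() + p.sum() + epsilon
    loss = 1.0 - (2.0 * inter + epsilon) / denom
    return loss if wrapped else loss.item()


def combined_loss(p_hat, p, config: LossConfig | None = None):
    """alpha * WCE + (1 - alpha) * Dice loss."""
    config = config or LossConfig()
    wce = weighted_cross_entropy(p_hat, p, config.beta, config.epsilon)
    dsc = dice_loss(p_hat, p, config.epsilon)
    return config.alpha * wce + (1.0 - config.alpha) * dsc
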