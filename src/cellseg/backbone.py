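"""U-shaped encoder-decoder backbone and full model assembly.

The encoder is the canonical U-Net contracting path (two 3x3 same-padded
convolutions with batch normalisation and ReLU per block, 2x2 max pooling
between stages); the decoder mirrors it with 2x2 transposed-convolution
upsampling.  Same padding keeps skip and decoder features aligned without
cropping.  The model variant decides what flows across the U:

* ``baseline``   - raw encoder features, plain concatenation (U-Net)
* ``ccf``        - channel cross-fusion outputs O_i, plain concatenation
* ``fc``         - raw encoder features joined by the gated feature connection
* ``ccf_fc``     - O_i joined by the gated feature connection
* ``lr_ccf_fc``  - as ``ccf_fc`` with rank-1 low-rank context injected into
  the cross-fusion tokens

The probability head is a 1x1 convolution followed by a sigmoid for a
single foreground class, or a channel softmax when ``out_classes >= 2``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import ModelConfig
from .cross_fusion import ChannelCrossFusion
from .feature_connection import FeatureConnection
from .low_rank import ContextGenerator
from .nn import (
    DTYPE,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Module,
    Tensor,
    concatenate,
)
from .nn import functional as F

__all__ = ["DoubleConv", "SegmentationModel", "predict_mask", "save_checkpoint", "load_checkpoint"]


class DoubleConv(Module):
    """conv3x3 -> BN -> ReLU, twice."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class _Upsample(Module):
    """Decoder upsampling: transposed 2x2 conv, or nearest + 1x1 conv."""

    def __init__(self, c_in: int, c_out: int, mode: str, rng: np.random.Generator):
        super().__init__()
        self.mode = mode
        if mode == "transposed":
            self.up = ConvTranspose2d(c_in, c_out, rng)
        elif mode == "nearest":
            self.proj = Conv2d(c_in, c_out, 1, rng)
        else:
            raise ValueError(f"unknown upsample mode {mode!r}")

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "transposed":
            return self.up(x)
        return self.proj(F.upsample_nearest(x, 2))


class SegmentationModel(Module):
    """Configurable U-shaped segmentation network."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c_in = config.in_channels
        for i in range(1, config.depth + 1):
            self.register_module(f"enc{i}", DoubleConv(c_in, config.stage_channels(i), rng))
            c_in = config.stage_channels(i)
        self.bottleneck = DoubleConv(c_in, 2 * c_in, rng)
        for i in range(config.depth, 0, -1):
            ci = config.stage_channels(i)
            self.register_module(f"up{i}", _Upsample(2 * ci, ci, config.upsample, rng))
            self.register_module(f"dec{i}", DoubleConv(2 * ci, ci, rng))
        self.head = Conv2d(config.stage_channels(1), config.out_classes, 1, rng)

        if config.uses_ccf:
            self.ccf = ChannelCrossFusion(config, rng)
        if config.uses_fc:
            for i in range(1, config.depth + 1):
                self.register_module(
                    f"fc{i}",
                    FeatureConnection(config.stage_channels(i), rng, config.fc_mode),
                )
        if config.uses_lr:
            for i in range(1, config.depth + 1):
                self.register_module(
                    f"ctx{i}", ContextGenerator(config.rank_L, config.lr_kernel, rng)
                )

    # ------------------------------------------------------------- encoder
    def encode(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Run the contracting path; returns per-stage features + bottleneck."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))
        if x.ndim != 4:
            raise ValueError("input must be (N, C, H, W)")
        self.config.validate_input_size(x.shape[2], x.shape[3])
        stages: list[Tensor] = []
        for i in range(1, self.config.depth + 1):
            x = self._modules[f"enc{i}"](x)
            stages.append(x)
            x = F.max_pool2d(x, 2)
        return stages, self.bottleneck(x)

    # ----------------------------------------------------------- skip path
    def fused_skips(self, stages: list[Tensor]) -> list[Tensor]:
        """The features that cross the U, per variant."""
        if not self.config.uses_ccf:
            return stages
        contexts = None
        if self.config.uses_lr:
            contexts = [
                self._modules[f"ctx{i + 1}"](stages[i]) for i in range(len(stages))
            ]
        return self.ccf(stages, contexts)

    # ------------------------------------------------------------- decoder
    def decode(self, bottleneck: Tensor, fused_skips: list[Tensor]) -> Tensor:
        """Expanding path consuming the fused skips; returns per-pixel scores."""
        x = bottleneck
        for i in range(self.config.depth, 0, -1):
            x = self._modules[f"up{i}"](x)
            skip = fused_skips[i - 1]
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(
                    f"decoder stage {i}: skip spatial {skip.shape[2:]} != "
                    f"decoder {x.shape[2:]}"
                )
            if self.config.uses_fc:
                x = self._modules[f"fc{i}"](skip, x)
            else:
                x = concatenate([skip, x], axis=1)
            x = self._modules[f"dec{i}"](x)
        return self.head(x)

    def forward(self, x: Tensor) -> Tensor:
        stages, bottom = self.encode(x)
        return self.decode(bottom, self.fused_skips(stages))

    # ---------------------------------------------------------- inference
    def probability(self, scores: Tensor) -> Tensor:
        """Class scores -> per-pixel probabilities (sigmoid or softmax head)."""
        if self.config.out_classes == 1:
            return scores.sigmoid()
        return scores.softmax(axis=1)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Eval-mode probability maps for a (N, C, H, W) image batch."""
        was_training = self.training
        self.eval()
        try:
            out = self.probability(self(Tensor(np.asarray(images, dtype=DTYPE))))
        finally:
            self.train(was_training)
        return out.data


def predict_mask(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a binary mask (ties go foreground)."""
    prob = np.asarray(prob)
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probability map must lie in [0, 1]")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (prob >= threshold).astype(np.uint8)


def save_checkpoint(model: SegmentationModel, path: str | Path) -> Path:
    """Weights as .npz plus a JSON sidecar recording the ModelConfig."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.config.to_dict(), indent=2))
    return path


def load_checkpoint(path: str | Path) -> SegmentationModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    config = ModelConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
    model = SegmentationModel(config)
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model
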