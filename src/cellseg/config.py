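"""Configuration dataclasses for the model, loss, training and data corpus."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

VARIANTS = ("baseline", "ccf", "fc", "ccf_fc", "lr_ccf_fc")

#: ablation-table row labels, in canonical order
VARIANT_LABELS = {
    "baseline": "Baseline(U-Net)",
    "ccf": "Baseline+CCF",
    "fc": "Baseline+FC",
    "ccf_fc": "Baseline+CCF+FC",
    "lr_ccf_fc": "Baseline+LR+CCF+FC",
}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``variant`` wires the skip path: ``baseline`` is plain U-Net
    concatenation; ``ccf`` routes encoder features through channel
    cross-fusion attention; ``fc`` joins skip and decoder features through
    the gated feature-connection block; ``lr_ccf_fc`` additionally injects
    the rank-1 direction context vectors into the attention tokens.
    """

    depth: int = 4
    base_channels: int = 64
    variant: str = "baseline"
    rank_L: int = 4
    heads_N: int = 4
    patch_size: int = 8
    out_classes: int = 1
    embed_dim: int = 64
    in_channels: int = 1
    upsample: str = "transposed"  # or "bilinear"
    fc_mode: str = "gate"  # or "add": rejected element-wise-addition reading
    lr_kernel: int = 3

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid: {', '.join(VARIANTS)}"
            )
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.patch_size % 2 ** (self.depth - 1) != 0 and self.uses_ccf:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)} so every stage "
                "yields the same token count"
            )
        if self.rank_L < 1:
            raise ValueError("rank_L must be >= 1")
        if self.heads_N < 1:
            raise ValueError("heads_N must be >= 1")

    @property
    def uses_ccf(self) -> bool:
        return self.variant in ("ccf", "ccf_fc", "lr_ccf_fc")

    @property
    def uses_fc(self) -> bool:
        return self.variant in ("fc", "ccf_fc", "lr_ccf_fc")

    @property
    def uses_lr(self) -> bool:
        return self.variant == "lr_ccf_fc"

    def stage_channels(self, i: int) -> int:
        """Channels at encoder stage ``i`` (1-based)."""
        return self.base_channels * 2 ** (i - 1)

    def validate_input_size(self, h: int, w: int) -> None:
        div = 2**self.depth
        for name, s in (("height", h), ("width", w)):
            if s % div != 0:
                raise ValueError(
                    f"input {name} {s} must be divisible by 2^depth = {div}"
                )
            if self.uses_ccf and s % self.patch_size != 0:
                raise ValueError(
                    f"input {name} {s} must be divisible by patch_size = "
                    f"{self.patch_size}"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class LossConfig:
    """Blend weight alpha, positive-class weight beta, Dice smoothing epsilon."""

    alpha: float = 0.5
    beta: float = 1.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class TrainConfig:
    """Optimisation schedule; defaults follow the reference protocol
    (Adam, 40 epochs, batch size 4, learning rate 1e-3, flip augmentation)."""

    epochs: int = 40
    batch_size: int = 4
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    augment: bool = True
    val_every: int = 1
    cosine_decay: bool = False
    macro_average: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if isinstance(self.loss, dict):
            self.loss = LossConfig(**self.loss)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cell-image corpus.

    Defaults emulate bright, roundish, frequently touching cells of varied
    radius on a darker textured background with additive Gaussian noise and
    a class-imbalanced foreground (well under 35% of pixels on average).
    """

    image_size: int = 64
    n_images: int = 100
    cells_min: int = 1
    cells_max: int = 6
    radius_min: float = 5.0
    radius_max: float = 14.0
    overlap_prob: float = 0.3
    noise_sigma: float = 0.1
    texture: float = 0.08
    eccentricity: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 8 or self.image_size & (self.image_size - 1):
            raise ValueError("image_size must be a power of two >= 8")
        if self.radius_max >= self.image_size / 2:
            raise ValueError("radius_max must be smaller than image_size/2")
        if not 0.0 <= self.overlap_prob <= 1.0:
            raise ValueError("overlap_prob must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must lie in [0, 1)")
        if self.cells_min < 0 or self.cells_max < self.cells_min:
            raise ValueError("invalid cells_min/cells_max range")
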