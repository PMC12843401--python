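"""Configuration objects: architecture, loss, training and augmentation.

The ``base`` preset is the reference configuration (224-px inputs, 16-px
patches, hidden dimension 768, 12 encoder layers); ``large`` doubles depth
and widens the hidden dimension to 1024; ``tiny`` is a CPU-sized variant
used for tests and desk-scale training runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = [
    "ConfigurationError",
    "ModelConfig",
    "LossConfig",
    "TrainConfig",
    "AugmentationPolicy",
    "PRESETS",
    "get_preset",
    "load_config",
    "save_config",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates a structural invariant."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``input_size`` and ``patch_size`` are in pixels; the token grid is
    ``input_size/patch_size`` per side. ``hidden_dim`` is the transformer
    width D, ``msga_groups`` the channel-group count G of the multi-scale
    gate, ``performer_features`` the number m of random features in the
    linear-attention kernel map, and ``lambda_init`` the initial value of
    the learnable Manhattan-bias strength (one scalar per head).
    """

    input_size: int = 224
    patch_size: int = 16
    hidden_dim: int = 768
    depth: int = 12
    mlp_dim: int | None = None  # defaults to 4*hidden_dim
    num_heads: int = 12
    msga_groups: int = 8
    stem_width: int = 64
    decoder_channels: tuple = (256, 128, 64, 16)
    num_classes: int = 9
    num_skips: int = 3
    performer_features: int = 256
    lambda_init: float = 1.0

    def __post_init__(self):
        self.decoder_channels = tuple(self.decoder_channels)
        if self.mlp_dim is None:
            self.mlp_dim = 4 * self.hidden_dim
        self.validate()

    # -- derived quantities --------------------------------------------------
    @property
    def grid_size(self) -> int:
        return self.input_size // self.patch_size

    @property
    def num_up_stages(self) -> int:
        return int(self.patch_size).bit_length() - 1  # log2(patch_size)

    @property
    def skip_stages(self) -> tuple:
        """Indices of up-stages whose output resolution matches a stem skip
        (1/2, 1/4 or 1/8 of the input side)."""
        return tuple(
            t for t in range(self.num_up_stages)
            if self.patch_size >> (t + 1) in (2, 4, 8)
        )

    def validate(self):
        def err(msg):
            raise ConfigurationError(msg)

        if self.input_size % self.patch_size:
            err(f"input_size={self.input_size} is not divisible by patch_size={self.patch_size}")
        if self.patch_size < 8 or self.patch_size & (self.patch_size - 1) or self.patch_size % 8:
            err(f"patch_size={self.patch_size} must be a power of two and a multiple of 8")
        if self.hidden_dim % self.num_heads:
            err(f"hidden_dim={self.hidden_dim} is not divisible by num_heads={self.num_heads}")
        if self.hidden_dim % self.msga_groups:
            err(f"hidden_dim={self.hidden_dim} is not divisible by msga_groups={self.msga_groups}")
        if len(self.decoder_channels) != self.num_up_stages:
            err(
                f"decoder_channels has {len(self.decoder_channels)} entries but "
                f"patch_size={self.patch_size} requires {self.num_up_stages} up-stages"
            )
        if self.num_skips > len(self.skip_stages):
            err(f"num_skips={self.num_skips} exceeds the available skip connections")
        if self.num_classes < 1:
            err("num_classes must be >= 1")
        if self.performer_features < 1:
            err("performer_features must be >= 1")
        if self.depth < 1:
            err("depth must be >= 1")


@dataclass
class LossConfig:
    """Compound-loss weights: total = lambda_ce * CE + lambda_dice * Dice."""

    lambda_ce: float = 0.5
    lambda_dice: float = 0.5
    smooth: float = 1e-5
    background_excluded: bool = True

    def __post_init__(self):
        if self.lambda_ce < 0 or self.lambda_dice < 0:
            raise ConfigurationError("loss weights must be nonnegative")


@dataclass
class TrainConfig:
    """SGD training protocol: lr 0.01, momentum 0.9, weight decay 1e-4,
    polynomial learning-rate decay (power 0.9) over ``max_iterations``."""

    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 24
    max_iterations: int = 20000
    lr_decay_power: float = 0.9
    seed: int = 0
    checkpoint_every: int = 1000
    augment: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError("lr must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class AugmentationPolicy:
    """On-the-fly training augmentation.

    Geometric transforms (flip, rotation, translation, scaling, elastic
    deformation) are applied jointly to image and mask; intensity
    transforms (brightness/contrast, Gaussian noise, CLAHE) to the image
    only. ``flip_prob`` 0.5 and ``rotate_limit`` 20 degrees are the stated
    policy; the remaining magnitudes are package defaults.
    """

    flip_prob: float = 0.5
    affine_prob: float = 0.5
    rotate_limit: float = 20.0       # degrees
    translate_frac: float = 0.10     # fraction of image side
    scale_range: tuple = (0.9, 1.1)
    elastic_prob: float = 0.3
    elastic_alpha: float = 30.0      # px displacement magnitude
    elastic_sigma: float = 5.0       # px smoothing
    occlusion_prob: float = 0.3
    occlusion_max_holes: int = 2
    occlusion_max_size: int = 16     # px
    brightness_contrast_prob: float = 0.5
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    noise_prob: float = 0.3
    noise_sigma: float = 0.02        # of the [0,1] intensity range
    clahe_prob: float = 0.2
    clahe_clip: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("flip_prob", "affine_prob", "elastic_prob", "occlusion_prob",
                     "brightness_contrast_prob", "noise_prob", "clahe_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} is not a probability")


PRESETS: dict[str, dict] = {
    "tiny": dict(input_size=64, patch_size=16, hidden_dim=64, depth=2, mlp_dim=128,
                 num_heads=4, msga_groups=4, stem_width=8,
                 decoder_channels=(32, 16, 16, 8), num_classes=4, num_skips=3,
                 performer_features=64),
    "base": dict(input_size=224, patch_size=16, hidden_dim=768, depth=12,
                 num_heads=12, msga_groups=8, stem_width=64,
                 decoder_channels=(256, 128, 64, 16), num_classes=9, num_skips=3,
                 performer_features=256),
    "large": dict(input_size=224, patch_size=16, hidden_dim=1024, depth=24,
                  num_heads=16, msga_groups=8, stem_width=64,
                  decoder_channels=(256, 128, 64, 16), num_classes=9, num_skips=3,
                  performer_features=256),
}


def get_preset(name: str, **overrides) -> ModelConfig:
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset '{name}' (choose from {sorted(PRESETS)})")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def load_config(path) -> dict:
    """Read a YAML config file with optional ``model``/``train``/``loss``/
    ``augment`` sections; ``model.preset`` selects a preset to override."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    model_raw = dict(raw.get("model", {}))
    preset = model_raw.pop("preset", None)
    out["model"] = get_preset(preset, **model_raw) if preset else ModelConfig(**model_raw)
    out["train"] = TrainConfig(**raw.get("train", {}))
    out["loss"] = LossConfig(**raw.get("loss", {}))
    aug_raw = dict(raw.get("augment", {}))
    if "scale_range" in aug_raw:
        aug_raw["scale_range"] = tuple(aug_raw["scale_range"])
    out["augment"] = AugmentationPolicy(**aug_raw)
    return out


def save_config(cfg: dict, path):
    payload = {}
    for key in ("model", "train", "loss", "augment"):
        if key in cfg:
            d = dataclasses.asdict(cfg[key])
            for k, v in d.items():
                if isinstance(v, tuple):
                    d[k] = list(v)
            payload[key] = d
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
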