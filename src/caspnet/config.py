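"""Run configuration: architecture, training, augmentation and split specs.

Defaults encode the published recipe: ViT-Base geometry (224 px input,
16 px patches, 12 blocks of 12 heads at 768 dims), CSP/SPPF widths of
384, a 768-512-256-5 classification head, AdamW with peak learning rate
1e-3 and weight decay 0.05, batch size 128, 450 epochs, one-cycle cosine
schedule, and the fixed seed 1337 with an 80:10:10 stratified holdout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

VARIANTS = ("full", "vit_only", "csp_sppf_only", "vit_csp")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class ArchConfig:
    """Every architectural hyperparameter of the hybrid classifier."""

    image_size: int = 224
    patch_size: int = 16
    in_channels: int = 3
    embed_dim: int = 768
    depth: int = 12
    num_heads: int = 12
    mlp_ratio: float = 4.0
    qkv_bias: bool = True
    dropout: float = 0.1
    attn_dropout: float = 0.1
    num_classes: int = 5
    csp_mid: int = 384
    sppf_mid: int = 384
    sppf_kernel: int = 5
    head_hidden: list = field(default_factory=lambda: [512, 256])
    variant: str = "full"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.image_size % self.patch_size != 0:
            raise ConfigError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}"
            )
        if self.embed_dim % self.num_heads != 0:
            raise ConfigError(
                f"embed_dim {self.embed_dim} not divisible by num_heads {self.num_heads}"
            )
        for name in (
            "image_size",
            "patch_size",
            "in_channels",
            "embed_dim",
            "depth",
            "num_heads",
            "num_classes",
            "csp_mid",
            "sppf_mid",
            "sppf_kernel",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("dropout", "attn_dropout"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {p}")
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; valid: {VARIANTS}")

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_size ** 2

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads


@dataclass
class TrainingConfig:
    """Optimizer, schedule and loop hyperparameters."""

    max_lr: float = 0.001
    initial_lr: float = 0.0001
    final_lr: float = 0.00001
    warmup_fraction: float = 0.1
    weight_decay: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 128
    epochs: int = 450
    seed: int = 1337

    def __post_init__(self):
        if not 0 < self.initial_lr <= self.max_lr:
            raise ConfigError("require 0 < initial_lr <= max_lr")
        if self.final_lr > self.initial_lr:
            raise ConfigError("require final_lr <= initial_lr")
        if self.weight_decay < 0:
            raise ConfigError("weight_decay must be >= 0")
        for b in (self.beta1, self.beta2):
            if not 0.0 < b < 1.0:
                raise ConfigError("betas must be in (0, 1)")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ConfigError("warmup_fraction must be in (0, 1)")


@dataclass
class AugmentationConfig:
    """Training-time augmentation, mirroring the published table."""

    crop_size: int = 224
    hflip_p: float = 0.5
    vflip_p: float = 0.5
    rotation_deg: float = 20.0
    brightness: float = 0.1
    contrast: float = 0.1
    saturation: float = 0.1
    hue: float = 0.1
    crop_scale: tuple = (0.6, 1.0)

    def __post_init__(self):
        for name in ("hflip_p", "vflip_p"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.rotation_deg < 0:
            raise ConfigError("rotation_deg must be >= 0")
        for name in ("brightness", "contrast", "saturation", "hue"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class SplitSpec:
    """Stratified holdout: 80:10:10 with a fixed seed."""

    train: float = 0.8
    val: float = 0.1
    test: float = 0.1
    seed: int = 1337

    def __post_init__(self):
        if min(self.train, self.val, self.test) <= 0:
            raise ConfigError("split ratios must be positive")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ConfigError("split ratios must sum to 1")


_SECTIONS = {
    "arch": ArchConfig,
    "training": TrainingConfig,
    "augmentation": AugmentationConfig,
    "split": SplitSpec,
}
_PATH_KEYS = {"data_root", "out_dir"}


@dataclass
class RunConfig:
    """Merged configuration for a whole run, loadable from YAML."""

    arch: ArchConfig = field(default_factory=ArchConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    data_root: str | None = None
    out_dir: str = "runs/default"

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - set(_SECTIONS) - _PATH_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            section = doc.get(name, {})
            if not isinstance(section, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(section) - valid
            if bad:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(bad)}")
            kwargs[name] = section_cls(**section)
        for key in _PATH_KEYS:
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        doc = {name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS}
        doc["augmentation"]["crop_scale"] = list(doc["augmentation"]["crop_scale"])
        doc["data_root"] = self.data_root
        doc["out_dir"] = self.out_dir
        return doc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
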