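"""Configuration dataclasses for the model, loss and training loop.

All architecture knobs live in :class:`ModelConfig`; ablation variants
(attention gates off, transformer bottleneck off, context-rich enrichment at
other encoder layers, serial vs parallel arrangement of the multi-scale
convolution and pooling branches) are expressed purely through configuration
so that every variant shares one implementation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError

VIT_PRESETS = {
    # (layers, hidden dim, MLP dim, heads)
    "base": (12, 768, 3072, 12),
    "large": (24, 1024, 4096, 16),
}


@dataclass
class ViTConfig:
    """Transformer bottleneck hyperparameters."""

    n_layers: int = 12
    hidden_dim: int = 768
    mlp_dim: int = 3072
    n_heads: int = 12
    patch_size: int = 1
    dropout: float = 0.0

    def __post_init__(self):
        if self.hidden_dim % self.n_heads:
            raise ConfigurationError(
                f"hidden_dim {self.hidden_dim} not divisible by n_heads {self.n_heads}")

    @classmethod
    def preset(cls, name: str, **overrides) -> "ViTConfig":
        try:
            layers, hidden, mlp, heads = VIT_PRESETS[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown ViT preset {name!r}; choose from {sorted(VIT_PRESETS)}")
        kw = dict(n_layers=layers, hidden_dim=hidden, mlp_dim=mlp, n_heads=heads)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class ModelConfig:
    """Full architecture description.

    The encoder channel schedule is ``stem_channels * (1, 2, 4, 8)`` at
    spatial scales 2, 4, 8, 16.  ``decoder_widths`` are the working widths at
    scales 8, 4, 2.
    """

    in_channels: int = 3
    stem_channels: int = 64
    msc_rates: tuple[int, ...] = (1, 2, 4, 8)
    msp_sizes: tuple[int, ...] = (2, 4, 8, 16)
    fusion_branch_width: int = 64
    vit: ViTConfig = field(default_factory=ViTConfig)
    image_size: int = 256          # reference size for the positional embedding
    use_vit: bool = True
    use_attention_gate: bool = True
    use_context_rich: bool = True
    context_rich_layers: tuple[int, ...] = (1,)
    context_rich_mode: str = "parallel"   # "parallel" | "serial"
    use_fusion: bool = True
    decoder_widths: tuple[int, ...] = (256, 128, 64)

    def __post_init__(self):
        if isinstance(self.vit, dict):
            self.vit = ViTConfig(**self.vit)
        for fld in ("msc_rates", "msp_sizes", "context_rich_layers", "decoder_widths"):
            setattr(self, fld, tuple(getattr(self, fld)))
        if self.image_size % 16:
            raise ConfigurationError("image_size must be divisible by 16")
        if self.context_rich_mode not in ("parallel", "serial"):
            raise ConfigurationError(
                f"context_rich_mode must be 'parallel' or 'serial', "
                f"got {self.context_rich_mode!r}")
        if any(l not in (1, 2, 3) for l in self.context_rich_layers):
            raise ConfigurationError("context_rich_layers must be a subset of (1,2,3)")
        if len(self.decoder_widths) != 3:
            raise ConfigurationError("decoder_widths must list widths for scales 8,4,2")

    @property
    def encoder_channels(self) -> tuple[int, int, int, int]:
        c = self.stem_channels
        return (c, 2 * c, 4 * c, 8 * c)

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Reduced-width preset for CPU-scale experiments and tests."""
        kw = dict(
            stem_channels=16,
            fusion_branch_width=16,
            vit=ViTConfig(n_layers=2, hidden_dim=64, mlp_dim=128, n_heads=4),
            image_size=64,
            decoder_widths=(64, 32, 16),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class LossWeights:
    """Convex weights (alpha, beta, gamma, theta) of the four loss terms:
    Dice, binary cross-entropy, SSIM and edge preservation."""

    alpha: float = 0.4
    beta: float = 0.3
    gamma: float = 0.15
    theta: float = 0.15

    def __post_init__(self):
        vals = (self.alpha, self.beta, self.gamma, self.theta)
        if any(v < 0 for v in vals):
            raise ConfigurationError(f"loss weights must be nonnegative, got {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"loss weights must sum to 1 (got {sum(vals)!r})")


@dataclass
class TrainConfig:
    """Optimization hyperparameters (SGD with momentum)."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0001
    epochs: int = 50
    batch_size: int = 4
    image_size: int = 256
    seed: int = 0
    ssim_window: int = 11
    edge_norm: str = "l1"
    loss: LossWeights = field(default_factory=LossWeights)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if isinstance(self.loss, dict):
            self.loss = LossWeights(**self.loss)
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)
        if self.image_size % 16:
            raise ConfigurationError("image_size must be divisible by 16")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(cfg, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def load_train_config(path) -> TrainConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return TrainConfig(**raw)


def load_model_config(path) -> ModelConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "model" in raw:   # accept a full train config file too
        raw = raw["model"]
    return ModelConfig(**raw)
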