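"""Model configuration: invariants, YAML round-trip, frozen reference config.

The reference configuration describes the multi-channel shifted-window
encoder–decoder at 48×48 input resolution: depthwise patch embedding with
12 filters per biomarker channel (latent depth C = 96 at 8 channels),
window-6 attention, two encoder scales plus a bottleneck (one merging
stage fewer than the 224×224 original), and exactly two skip connections.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from importlib import resources

import yaml

__all__ = ["ModelConfig", "ConfigurationError", "reference_config", "compact_config"]


class ConfigurationError(ValueError):
    """Raised when a ModelConfig violates a structural invariant."""


@dataclass
class ModelConfig:
    """Hyper-parameters of the multi-channel Swin encoder–decoder.

    ``stage_depths`` lists transformer-block counts per encoder scale with
    the bottleneck last; shifted-window pairs are stages of depth 2.  The
    bottleneck grid (3×3 at defaults) fits inside a single attention
    window, where a shifted partner block would attend to the same tokens,
    so the reference bottleneck holds a single block.
    """

    input_size: int = 48
    patch_size: int = 4
    in_channels: int = 8
    filters_per_channel: int = 12
    window_size: int = 6
    shift_size: int | None = None          # None -> window_size // 2
    stage_depths: tuple[int, ...] = (2, 2, 1)   # encoder scales, bottleneck last
    decoder_depths: tuple[int, ...] | None = None  # None -> mirror of encoder scales
    heads_per_stage: tuple[int, ...] = (3, 6, 12)
    mlp_ratio: float = 4.0
    num_classes: int = 11
    use_relative_position_bias: bool = True
    qkv_bias: bool = True
    embed_norm: bool = True                # layer norm after patch embedding
    embed_bias: bool = True
    attention_scale: str = "per_head_sqrt"  # scores scaled by sqrt(head depth)

    def __post_init__(self):
        self.stage_depths = tuple(self.stage_depths)
        if self.decoder_depths is not None:
            self.decoder_depths = tuple(self.decoder_depths)
        self.heads_per_stage = tuple(self.heads_per_stage)
        self.validate()

    # -- derived ---------------------------------------------------------
    @property
    def embed_dim(self) -> int:
        return self.in_channels * self.filters_per_channel

    @property
    def grid_size(self) -> int:
        return self.input_size // self.patch_size

    @property
    def num_scales(self) -> int:
        return len(self.stage_depths)

    @property
    def effective_shift(self) -> int:
        return self.window_size // 2 if self.shift_size is None else self.shift_size

    def scale_dim(self, scale: int) -> int:
        return self.embed_dim * (2**scale)

    def scale_side(self, scale: int) -> int:
        return self.grid_size // (2**scale)

    def effective_window(self, scale: int) -> int:
        """Window shrinks to the grid when the grid is smaller."""
        return min(self.window_size, self.scale_side(scale))

    def resolved_decoder_depths(self) -> tuple[int, ...]:
        if self.decoder_depths is not None:
            return self.decoder_depths
        return tuple(reversed(self.stage_depths[:-1]))

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        errs = []
        if self.input_size % self.patch_size != 0:
            errs.append("input_size must be divisible by patch_size")
        if self.window_size < 1:
            errs.append("window_size must be positive")
        if self.effective_shift >= self.window_size:
            errs.append("shift_size must be smaller than window_size")
        if len(self.heads_per_stage) != len(self.stage_depths):
            errs.append("heads_per_stage must match stage_depths in length")
        if self.num_classes < 2:
            errs.append("num_classes must be at least 2")
        if self.attention_scale not in ("per_head_sqrt", "full_depth"):
            errs.append("attention_scale must be 'per_head_sqrt' or 'full_depth'")
        for s in range(len(self.stage_depths)):
            side = self.scale_side(s)
            if side < 1:
                errs.append(f"token grid vanishes at scale {s}; too many merging stages")
                continue
            w = self.effective_window(s)
            if side % w != 0:
                errs.append(
                    f"token grid side {side} at scale {s} not divisible by window {w}"
                )
            if self.scale_dim(s) % self.heads_per_stage[s] != 0:
                errs.append(
                    f"heads ({self.heads_per_stage[s]}) must divide depth "
                    f"{self.scale_dim(s)} at scale {s}"
                )
        if errs:
            raise ConfigurationError("; ".join(errs))

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("stage_depths", "decoder_depths", "heads_per_stage"):
            if d[k] is not None:
                d[k] = list(d[k])
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def reference_config(num_classes: int = 11) -> ModelConfig:
    """The frozen reference configuration shipped with the package.

    At ``num_classes=11`` (ten anatomical regions plus background) the
    built model has exactly 4,990,032 trainable parameters.
    """
    text = resources.files("mcswin").joinpath("reference_config.yaml").read_text()
    cfg = ModelConfig.from_yaml(text)
    if num_classes != cfg.num_classes:
        d = cfg.to_dict()
        d["num_classes"] = num_classes
        cfg = ModelConfig.from_dict(d)
    return cfg


def compact_config(num_classes: int = 4, in_channels: int = 8) -> ModelConfig:
    """Reduced-width variant (3 filters per channel, narrow MLP) for
    CPU-scale experiments on synthetic phantoms; same topology as the
    reference model."""
    return ModelConfig(
        in_channels=in_channels,
        filters_per_channel=3,
        heads_per_stage=(2, 4, 8),
        mlp_ratio=2.0,
        num_classes=num_classes,
    )
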