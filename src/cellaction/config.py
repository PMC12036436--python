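"""Run configuration.

A :class:`RunConfig` gathers every tunable of the pipeline: the KNN
candidate count ``knn_k``, the memory-kernel decay ``memory_lambda`` in
[0, 1] and window ``memory_window`` (L), the velocity weight in the
configuration vector, the PCA dimension ``n_pcs``, the per-layer
vocabulary size, sampler settings, transformer hyperparameters, and the
single master seed from which every stochastic stage derives its own
named substream.

Config files are flat ``key: value`` text (a YAML subset); nested
``sampler`` and ``model`` blocks are plain mappings.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._errors import ValidationError
from .generation import SamplerSettings

__all__ = ["ModelConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class ModelConfig:
    """Transformer hyperparameters (desk-scale defaults)."""

    n_layers: int = 2
    width: int = 64
    n_heads: int = 4
    epochs: int = 200
    learning_rate: float = 1e-2
    batch_size: int = 64
    holdout_fraction: float = 0.2
    patience: int = 25

    def __post_init__(self) -> None:
        if self.width % self.n_heads != 0:
            raise ValidationError("width must be divisible by n_heads")
        for name in ("n_layers", "width", "n_heads", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not (0 < self.holdout_fraction < 1):
            raise ValidationError("holdout_fraction must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    knn_k: int = 30
    memory_lambda: float = 0.0
    memory_window: int = 1
    velocity_weight: float = 1.0
    n_pcs: int = 30
    vocab_size: int = 50
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.memory_lambda <= 1.0):
            raise ValidationError(
                f"memory_lambda must lie in [0, 1], got {self.memory_lambda}"
            )
        if self.knn_k < 1:
            raise ValidationError("knn_k must be a positive integer")
        if self.memory_window < 1:
            raise ValidationError("memory_window must be a positive integer")
        if self.velocity_weight < 0:
            raise ValidationError("velocity_weight must be >= 0")
        if self.n_pcs < 1:
            raise ValidationError("n_pcs must be a positive integer")
        if self.vocab_size < 1:
            raise ValidationError("vocab_size must be a positive integer")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat YAML config file into a validated :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} must be a key-value mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "sampler" in raw:
        raw["sampler"] = SamplerSettings(**raw["sampler"])
    if "model" in raw:
        raw["model"] = ModelConfig(**raw["model"])
    return RunConfig(**raw)
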