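"""Run configuration: YAML-backed, schema-validated, fully defaulted.

Defaults follow the pipeline's reference protocol: 224x224 inputs, focal
gamma 2.0, fusion weights (0.6, 0.4), five folds, masking threshold 128.
Unknown keys are rejected and all schema violations are reported together.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Carries the full list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_default=True)


class DataConfig(_Block):
    image_dir: str | None = None
    label_csv: str | None = None
    id_column: str | None = None
    exclude_columns: tuple[str, ...] = ()


class ModelConfig(_Block):
    backbones: tuple[str, str] = ("vgg19", "resnet50")
    stage1_backbone: str | None = None  # defaults to backbones[0]
    input_size: int = 224


class TrainingConfig(_Block):
    epochs: int = 200
    batch_size: int = 16
    lr_init: float = 1e-4
    lr_floor: float = 1e-7
    lr_factor: float = 0.1
    lr_patience_epochs: int = 8
    early_stop_patience: int = 20
    folds: int = 5
    gamma: float = 2.0
    use_class_weights: bool = True
    use_classic_augment: bool = True

    @model_validator(mode="after")
    def _ranges(self):
        if not (0 < self.lr_floor <= self.lr_init):
            raise ValueError("need 0 < lr_floor <= lr_init")
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        return self


class AttentionConfig(_Block):
    theta: float = 128.0
    source: str = "gradcam"  # or "guided_gradcam"
    aggregate: str = "true_labels"  # or "predicted"
    enabled: bool = True

    @model_validator(mode="after")
    def _ranges(self):
        if not 0 <= self.theta <= 255:
            raise ValueError("theta must lie in [0, 255]")
        if self.source not in ("gradcam", "guided_gradcam"):
            raise ValueError(f"unknown attention source {self.source!r}")
        return self


class FusionConfig(_Block):
    lam: float = 0.6
    sigma: float = 0.4

    @model_validator(mode="after")
    def _convex(self):
        if abs(self.lam + self.sigma - 1.0) > 1e-9:
            raise ValueError(f"fusion weights must satisfy lam + sigma = 1, "
                             f"got {self.lam} + {self.sigma}")
        return self


class MetricsConfig(_Block):
    decision_threshold: float = 0.5
    averaging_mode: str = "micro"

    @model_validator(mode="after")
    def _ranges(self):
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.averaging_mode not in ("micro", "macro"):
            raise ValueError(f"unknown averaging mode {self.averaging_mode!r}")
        return self


class RunConfig(_Block):
    data: DataConfig = DataConfig()
    model: ModelConfig = ModelConfig()
    training: TrainingConfig = TrainingConfig()
    attention: AttentionConfig = AttentionConfig()
    fusion: FusionConfig = FusionConfig()
    metrics: MetricsConfig = MetricsConfig()
    seed: int = 0


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; missing keys fall back to defaults.

    All schema violations (unknown keys, range errors, the lam+sigma
    constraint) are collected into one :class:`ConfigError`.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError([f"top level of {path} must be a mapping"])
        raw = loaded
    if overrides:
        raw = _deep_merge(raw, overrides)
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            msgs.append(f"{loc}: {err['msg']}")
        raise ConfigError(msgs) from None


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
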