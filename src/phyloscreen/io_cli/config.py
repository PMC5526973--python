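"""Pipeline configuration with validation and YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    focal_condition: str
    comparison_conditions: list[str]
    control_condition: str | None = None
    fold_threshold: float = 2.0
    alpha: float = 0.05
    go_alpha: float = 0.01
    effect_r_threshold: float = 0.5
    power_threshold: float = 0.8
    promoter_length: int = 5000
    network_thresholds: list[float] = field(
        default_factory=lambda: [0.15, 0.4, 0.7, 0.9])
    seed: int = 0
    t_variant: str = "welch"
    reference_genes: list[str] = field(default_factory=list)
    calibrator_condition: str | None = None

    def __post_init__(self) -> None:
        if not self.focal_condition:
            raise ConfigError("focal_condition must be set")
        if not self.comparison_conditions:
            raise ConfigError("at least one comparison condition required")
        if self.focal_condition in self.comparison_conditions:
            raise ConfigError(
                "focal_condition must not appear in comparison_conditions")
        if len(set(self.comparison_conditions)) != len(self.comparison_conditions):
            raise ConfigError("comparison_conditions contains duplicates")
        if self.fold_threshold <= 0:
            raise ConfigError("fold_threshold must be positive")
        for name in ("alpha", "go_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.effect_r_threshold < 1.0:
            raise ConfigError("effect_r_threshold must lie in [0, 1)")
        if not 0.0 < self.power_threshold < 1.0:
            raise ConfigError("power_threshold must lie in (0, 1)")
        if self.promoter_length <= 0:
            raise ConfigError("promoter_length must be a positive integer")
        for t in self.network_thresholds:
            if not 0.0 < t <= 1.0:
                raise ConfigError("network thresholds must lie in (0, 1]")
        if self.t_variant not in ("welch", "student"):
            raise ConfigError("t_variant must be 'welch' or 'student'")

    @property
    def conditions(self) -> list[str]:
        """All conditions: focal, comparisons, then control if present."""
        out = [self.focal_condition, *self.comparison_conditions]
        if self.control_condition and self.control_condition not in out:
            out.append(self.control_condition)
        return out

    @property
    def calibrator(self) -> str:
        """qPCR calibrator; defaults to the control condition."""
        cal = self.calibrator_condition or self.control_condition
        if cal is None:
            raise ConfigError(
                "no calibrator: set calibrator_condition or control_condition")
        return cal

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(
                f"missing required config field(s): {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
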