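"""Pipeline configuration: one YAML/JSON document with strict validation.

Unknown keys are rejected so typos cannot silently fall back to defaults.
The ambient illumination range is carried as metadata only (the room light
under which measurements were taken); it does not enter any computation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .cohort import DEFAULT_AGE_BRACKETS, GeneratorDefaults
from .protocol import ProtocolTimeline, build_default_timeline
from .render import DEFAULT_FOCAL_LENGTH_MM, DEFAULT_PIXEL_PITCH_MM


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values."""


@dataclass
class PipelineConfig:
    timeline: list[dict] = field(
        default_factory=lambda: build_default_timeline().to_config()
    )
    sample_rate_hz: float = 60.0
    generator: GeneratorDefaults = field(default_factory=GeneratorDefaults)
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    focal_length_mm: float = DEFAULT_FOCAL_LENGTH_MM
    alpha: float = 0.05
    alpha_normality: float = 0.05
    seed: int = 0
    ambient_lux_range: tuple[float, float] = (1049.0, 1133.0)

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 1.0:
            raise ConfigError("sample_rate_hz must exceed 1 Hz")
        for name in ("pixel_pitch_mm", "focal_length_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("alpha", "alpha_normality"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        if not 0 <= self.generator.anisocoria_mm < 3:
            raise ConfigError("anisocoria_mm must be in [0, 3) mm")
        if self.generator.noise_sd_mm < 0:
            raise ConfigError("noise_sd_mm must be >= 0")

    def build_timeline(self) -> ProtocolTimeline:
        return ProtocolTimeline.from_config(self.timeline)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ambient_lux_range"] = list(self.ambient_lux_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "generator" in data and isinstance(data["generator"], dict):
            gen_known = {f.name for f in fields(GeneratorDefaults)}
            gen_unknown = set(data["generator"]) - gen_known
            if gen_unknown:
                raise ConfigError(f"unknown generator keys: {sorted(gen_unknown)}")
            data["generator"] = GeneratorDefaults(**data["generator"])
        if "ambient_lux_range" in data:
            data["ambient_lux_range"] = tuple(data["ambient_lux_range"])
        return cls(**data)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load YAML or JSON config; None yields the frozen defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
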