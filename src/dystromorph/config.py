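"""Pipeline configuration: one YAML file, strictly validated.

Unknown keys are a hard error (misspelled options must not fall back to
silent defaults).  Sub-sections map onto the per-module config dataclasses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fibers import MorphometryConfig
from .stats import DecisionConfig


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    um_per_px: float = 1.0
    um_per_vox: float = 8.0
    seed: int = 0
    out_dir: str = "."
    fibers: MorphometryConfig = field(default_factory=MorphometryConfig)
    stats: DecisionConfig = field(default_factory=DecisionConfig)

    def __post_init__(self) -> None:
        if self.um_per_px <= 0 or self.um_per_vox <= 0:
            raise ConfigError("calibrations must be positive")


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    sub = {}
    if "fibers" in raw:
        sub["fibers"] = _build(MorphometryConfig, raw.pop("fibers"), "fibers")
    if "stats" in raw:
        stats_raw = raw.pop("stats")
        if "star_thresholds" in stats_raw:
            stats_raw["star_thresholds"] = tuple(stats_raw["star_thresholds"])
        sub["stats"] = _build(DecisionConfig, stats_raw, "stats")
    top = {f.name for f in dataclasses.fields(PipelineConfig)} - {"fibers", "stats"}
    unknown = set(raw) - top
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw, **sub)
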