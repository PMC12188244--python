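"""Structured pipeline configuration (YAML or JSON) with validated defaults."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .waveform import DetectionConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DGEThresholds:
    min_fc: float = 4.0
    max_fdr: float = 0.001
    expressed_min_prop: float = 0.5

    def validate(self, prefix: str = "dge") -> None:
        if self.min_fc < 1:
            raise ConfigError(f"{prefix}.min_fc must be >= 1")
        if not 0 < self.max_fdr <= 1:
            raise ConfigError(f"{prefix}.max_fdr must be in (0, 1]")
        if not 0 <= self.expressed_min_prop <= 1:
            raise ConfigError(f"{prefix}.expressed_min_prop must be in [0, 1]")


@dataclass(frozen=True)
class EnrichThresholds:
    minsetsize: int = 20
    max_fdr: float = 0.01
    min_s: float = 0.1
    delta: float = 0.1

    def validate(self, prefix: str = "enrichment") -> None:
        if self.minsetsize < 1:
            raise ConfigError(f"{prefix}.minsetsize must be >= 1")
        if not 0 < self.max_fdr <= 1:
            raise ConfigError(f"{prefix}.max_fdr must be in (0, 1]")
        if not 0 <= self.min_s < 1:
            raise ConfigError(f"{prefix}.min_s must be in [0, 1)")
        if self.delta < 0:
            raise ConfigError(f"{prefix}.delta must be >= 0")


@dataclass(frozen=True)
class StatsThresholds:
    alpha: float = 0.05
    cv_window: int = 5
    cv_max: float = 0.05

    def validate(self, prefix: str = "stats") -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"{prefix}.alpha must be in (0, 1)")
        if self.cv_window < 2:
            raise ConfigError(f"{prefix}.cv_window must be >= 2")
        if self.cv_max <= 0:
            raise ConfigError(f"{prefix}.cv_max must be positive")


@dataclass(frozen=True)
class SimulateScale:
    """Size of the synthetic inputs used by --simulate runs."""

    n_genes: int = 2000
    n_sets: int = 60
    n_enriched_sets: int = 6
    planted_per_class: int = 10
    effect: float = 6.0
    snippets_per_session: int = 4
    days: tuple = (0, 1, 8)

    def validate(self, prefix: str = "simulate") -> None:
        if self.n_genes < 10:
            raise ConfigError(f"{prefix}.n_genes must be >= 10")
        if self.n_sets < 0 or self.n_enriched_sets < 0:
            raise ConfigError(f"{prefix}: set counts must be >= 0")
        if self.snippets_per_session < 1:
            raise ConfigError(f"{prefix}.snippets_per_session must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    dge: DGEThresholds = field(default_factory=DGEThresholds)
    enrichment: EnrichThresholds = field(default_factory=EnrichThresholds)
    stats: StatsThresholds = field(default_factory=StatsThresholds)
    simulate: SimulateScale = field(default_factory=SimulateScale)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        # DetectionConfig validates in its own __post_init__
        self.dge.validate()
        self.enrichment.validate()
        self.stats.validate()
        self.simulate.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "detection": DetectionConfig,
    "dge": DGEThresholds,
    "enrichment": EnrichThresholds,
    "stats": StatsThresholds,
    "simulate": SimulateScale,
}


def config_from_dict(data: Optional[dict]) -> PipelineConfig:
    data = dict(data or {})
    kwargs = {}
    for section, cls in _SECTIONS.items():
        raw = data.pop(section, {}) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown key(s) in {section}: {sorted(unknown)}")
        if section == "simulate" and "days" in raw:
            raw["days"] = tuple(raw["days"])
        try:
            kwargs[section] = cls(**raw)
        except ValueError as exc:
            raise ConfigError(f"{section}: {exc}") from exc
    seed = data.pop("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    if data:
        raise ConfigError(f"unknown top-level key(s): {sorted(data)}")
    return PipelineConfig(seed=seed, **kwargs).validate()


def load_config(path) -> PipelineConfig:
    """Read a YAML (or JSON, a YAML subset) config; missing keys default."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is not None and not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(data)


def dump_config(cfg: PipelineConfig, path) -> None:
    data = cfg.to_dict()
    data["simulate"]["days"] = list(data["simulate"]["days"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
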