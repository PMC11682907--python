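"""Pipeline configuration: one YAML file controls paths, thresholds,
generator coefficients, model options and seeds."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .preproc import AoiGeometry, QcThresholds, default_geometry
from .synth import AcquisitionConfig, ArtifactSpec, GenerativeCoefficients, TraitConfig


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, with study defaults."""

    out_dir: str = "out"
    samples_path: str | None = None
    trials_path: str | None = None
    participants_path: str | None = None
    seed: int = 0
    n_control: int = 44
    n_mdd: int = 28
    dv: str = "dwell"  # DV for the moderation models: "dwell" or "bias"
    log_level: str = "INFO"
    traits: TraitConfig = field(default_factory=TraitConfig)
    coefficients: GenerativeCoefficients = field(default_factory=GenerativeCoefficients)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    geometry: AoiGeometry = field(default_factory=default_geometry)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "traits": TraitConfig,
    "coefficients": GenerativeCoefficients,
    "artifacts": ArtifactSpec,
    "acquisition": AcquisitionConfig,
    "thresholds": QcThresholds,
    "geometry": AoiGeometry,
}


def _build_section(cls, payload: Mapping[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown keys in config section {cls.__name__}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in payload.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Load a YAML config (missing file fields fall back to defaults) and
    apply flat overrides such as ``{"seed": 7, "thresholds.gap_ms": 66}``."""
    payload: dict[str, Any] = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
    cfg_kwargs: dict[str, Any] = {}
    for key, value in payload.items():
        if key in _SECTION_TYPES:
            cfg_kwargs[key] = _build_section(_SECTION_TYPES[key], value or {})
        else:
            cfg_kwargs[key] = value
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(cfg_kwargs) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**cfg_kwargs)
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if "." in key:
            section, leaf = key.split(".", 1)
            obj = getattr(cfg, section)
            setattr(cfg, section, dataclasses.replace(obj, **{leaf: value}))
        else:
            setattr(cfg, key, value)
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
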