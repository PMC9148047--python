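"""Run configuration: YAML-backed, validated, round-trippable.

A config file is a nested key-value document with sections ``geometry``,
``grid``, ``em``, ``thermal``, ``experiment`` and ``output``.  Interface
units follow the device datasheet conventions (cm, MHz implied Hz, W, degC,
s); everything is converted to SI at the module boundaries.  An empty file
yields the full default prototype configuration.  Unknown keys are rejected
and all schema violations are reported together.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .dosimetry import VOISpec
from .em import RunControl, SourceSpec
from .geometry import ApplicatorGeometry, GridSpec
from .thermal import Controller

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass(frozen=True)
class ThermalConfig:
    dt_s: float = 1.0
    t_ext_C: float = 21.5
    snapshot_every_s: float = 10.0
    metal_mode: str = "transparent"


@dataclass(frozen=True)
class ExperimentConfig:
    power_levels_W: tuple[float, ...] = (2.5, 3.0, 3.6)
    heat_duration_s: float = 2400.0
    cool_duration_s: float = 600.0
    focus_power_W: float = 5.0
    focus_heat_s: float = 300.0
    ir_delay_s: float = 180.0
    target_C: float = 43.0
    maintain_duration_s: float = 720.0
    seed: int = 0


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "coaxtherm_out"
    write_vtk: bool = True
    write_csv: bool = True


@dataclass(frozen=True)
class RunConfig:
    geometry: ApplicatorGeometry = field(default_factory=ApplicatorGeometry)
    grid: GridSpec = field(default_factory=GridSpec)
    source: SourceSpec = field(default_factory=SourceSpec)
    em: RunControl = field(default_factory=RunControl)
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    controller: Controller = field(default_factory=Controller)
    voi: VOISpec = field(default_factory=VOISpec)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            section = getattr(self, f.name)
            out[f.name] = {
                sf.name: _plain(getattr(section, sf.name)) for sf in dc_fields(section)
            }
        return out


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    return v


_SECTION_TYPES = {f.name: f.default_factory for f in dc_fields(RunConfig)}


def _build_section(name: str, cls_factory, data: dict, errors: list[str]):
    cls = cls_factory().__class__
    valid = {f.name: f for f in dc_fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            errors.append(f"{name}.{key}: unknown key")
            continue
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        bad = ", ".join(f"{name}.{k}" for k in kwargs) or name
        errors.append(f"{name}: {exc} (keys given: {bad})")
        return cls_factory()


def load_config(path) -> RunConfig:
    """Load a YAML config; an empty file yields the default prototype setup."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError([f"top level must be a mapping, got {type(raw).__name__}"])
    errors: list[str] = []
    sections = {}
    for key, value in raw.items():
        if key not in _SECTION_TYPES:
            errors.append(f"{key}: unknown section")
            continue
        if value is None:
            continue
        if not isinstance(value, dict):
            errors.append(f"{key}: section must be a mapping")
            continue
        sections[key] = _build_section(key, _SECTION_TYPES[key], value, errors)
    if errors:
        raise ConfigError(errors)
    return RunConfig(**sections)


def save_config(config: RunConfig, path) -> Path:
    """Write the fully resolved configuration next to run outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
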