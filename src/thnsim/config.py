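"""Flat key-value (YAML) configuration for the full parameter bundle.

Config keys mirror the dataclass field names bit-exactly; unknown keys are
rejected; missing keys take the documented defaults. Probabilities in config
files are fractions, never percentages.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, fields, replace

import yaml

from .params import (
    BystanderParams,
    EconomicParams,
    JailParams,
    ParamDraw,
    PopulationParams,
    RiskParams,
    SimulationSettings,
)

__all__ = ["ModelConfig", "ConfigError", "load_config", "serialize_config", "apply_draw"]


class ConfigError(ValueError):
    """Malformed configuration document or unknown key."""


@dataclass(frozen=True)
class ModelConfig:
    """The full parameter bundle for one simulation."""

    risk: RiskParams = RiskParams()
    bystander: BystanderParams = BystanderParams()
    jail: JailParams = JailParams()
    population: PopulationParams = PopulationParams()
    economics: EconomicParams = EconomicParams()
    sim: SimulationSettings = SimulationSettings()


# section name -> dataclass, built once; field names are globally unique.
_SECTIONS = {
    "risk": RiskParams,
    "bystander": BystanderParams,
    "jail": JailParams,
    "population": PopulationParams,
    "economics": EconomicParams,
    "sim": SimulationSettings,
}

_KEY_TO_SECTION: dict[str, str] = {}
for _sec, _cls in _SECTIONS.items():
    for _f in fields(_cls):
        assert _f.name not in _KEY_TO_SECTION, f"duplicate config key {_f.name}"
        _KEY_TO_SECTION[_f.name] = _sec


def load_config(source=None) -> ModelConfig:
    """Build a ModelConfig from a YAML path, YAML text, a mapping, or None.

    An empty document yields the all-defaults bundle. Unknown keys raise
    ConfigError naming the key; out-of-range values raise ValueError from the
    parameter dataclass that owns them.
    """
    if source is None:
        data = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        text = None
        if isinstance(source, os.PathLike):
            text = open(os.fspath(source)).read()
        elif isinstance(source, str):
            if "\n" not in source and os.path.exists(source):
                text = open(source).read()
            else:
                text = source
        elif hasattr(source, "read"):
            text = source.read()
        else:
            raise ConfigError(f"cannot read config from {type(source).__name__}")
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config does not parse as YAML: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a flat key-value document")

    per_section: dict[str, dict] = {sec: {} for sec in _SECTIONS}
    for key, value in data.items():
        sec = _KEY_TO_SECTION.get(key)
        if sec is None:
            raise ConfigError(f"unknown configuration key {key!r}")
        per_section[sec][key] = tuple(value) if key == "age_dist" else value
    kwargs = {sec: cls(**per_section[sec]) for sec, cls in _SECTIONS.items()}
    return ModelConfig(**kwargs)


def serialize_config(cfg: ModelConfig) -> str:
    """Emit the fully-resolved flat YAML document (round-trips exactly)."""
    flat = {}
    for sec in _SECTIONS:
        obj = getattr(cfg, sec)
        for f in fields(obj):
            v = getattr(obj, f.name)
            flat[f.name] = list(v) if isinstance(v, tuple) else v
    return yaml.safe_dump(flat, sort_keys=False)


def apply_draw(cfg: ModelConfig, draw: ParamDraw) -> ModelConfig:
    """Overlay one sensitivity draw onto a base configuration."""
    pop = replace(cfg.population,
                  frac_inmates_iou=draw.frac_inmates_iou,
                  frac_inmates_niou=draw.frac_inmates_niou)
    byst = replace(draw.bystander,
                   eff_naloxone=cfg.bystander.eff_naloxone,
                   eff_ems=cfg.bystander.eff_ems)
    return dataclasses.replace(cfg, risk=draw.risk, bystander=byst, population=pop)
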