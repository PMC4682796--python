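"""YAML configuration: load/validate/save a full treatment scenario.

The config file mirrors the parameter dataclasses one section per group
(grid, vessels, growth, oxygen, angiogenesis, formulation, drug) plus the
top-level run controls (seed, injection_day, horizon_h, ...). Unknown keys
are rejected with an error naming the key; omitted keys take the documented
defaults, so an empty file is a valid default scenario. A loaded scenario
round-trips losslessly through :func:`save_config`.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import yaml

from .angiogenesis import AngiogenesisParams
from .drug import DrugParams
from .efficacy import TreatmentScenario, VesselParams
from .grid import GridSpec
from .nanoparticle import NPFormulation
from .oxygen import OxygenParams
from .tumor import GrowthParams

__all__ = ["ConfigError", "load_config", "save_config", "scenario_to_dict",
           "SCHEMA_VERSION"]

logger = logging.getLogger("nanovasc")

SCHEMA_VERSION = 1

_SECTIONS = {
    "grid": GridSpec,
    "vessels": VesselParams,
    "growth": GrowthParams,
    "oxygen": OxygenParams,
    "angiogenesis": AngiogenesisParams,
    "formulation": NPFormulation,
    "drug": DrugParams,
}

_TOP_LEVEL = {
    f.name for f in dataclasses.fields(TreatmentScenario)
} - set(_SECTIONS)


class ConfigError(ValueError):
    pass


def _build_section(name: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{name}' "
            f"(valid: {sorted(valid)})"
        )
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section '{name}': {exc}") from exc


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> TreatmentScenario:
    """Parse and validate a YAML scenario file (None/empty -> all defaults).

    ``overrides`` is an optional {section.key or key: value} mapping applied
    after the file (used by the CLI); provenance is logged.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    for k, v in (overrides or {}).items():
        if "." in k:
            sec, key = k.split(".", 1)
            raw.setdefault(sec, {})[key] = v
        else:
            raw[k] = v

    raw = dict(raw)
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")

    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(name, cls, raw.pop(name, {}))
    unknown = set(raw) - _TOP_LEVEL
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)} "
            f"(valid sections: {sorted(_SECTIONS)}; "
            f"valid keys: {sorted(_TOP_LEVEL)})"
        )
    try:
        scenario = TreatmentScenario(**kwargs, **raw)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid top-level value: {exc}") from exc
    logger.info("loaded config from %s (overrides: %s)", path, overrides or {})
    return scenario


def scenario_to_dict(scenario: TreatmentScenario) -> dict:
    out: dict = {"schema_version": SCHEMA_VERSION}
    for name in _SECTIONS:
        out[name] = dataclasses.asdict(getattr(scenario, name))
    for key in _TOP_LEVEL:
        out[key] = getattr(scenario, key)
    return out


def save_config(scenario: TreatmentScenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario),
                                         sort_keys=True))
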