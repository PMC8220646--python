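"""Config-file loading (YAML or JSON) for experiments and the CLI."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .demand_model import CareLevelMultipliers
from .economics import CostParameters, EffectEstimates
from .errors import ConfigurationError
from .experiments import ExperimentConfig
from .shift_engine import SimulatorConfig
from .synthetic_hospital import GeneratorConfig

__all__ = ["load_config", "experiment_config_from_dict"]


def _check_keys(block: dict, allowed, where: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ConfigurationError(f"unknown key(s) in '{where}': {sorted(unknown)}")


def _build(cls, block: dict, where: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    _check_keys(block, fields, where)
    coerced = {}
    for name, value in block.items():
        if isinstance(value, list) and isinstance(fields[name].default, tuple):
            value = tuple(value)
        coerced[name] = value
    try:
        return cls(**coerced)
    except TypeError as exc:
        raise ConfigurationError(f"invalid '{where}' block: {exc}") from exc


def _costs_from_dict(block: dict) -> CostParameters:
    _check_keys(
        block, ("hourly_cost", "unsocial_multiplier", "excess_bed_day_cost", "currency"), "costs"
    )
    kwargs = {}
    if "hourly_cost" in block:
        kwargs["hourly_cost"] = {
            (role, source): float(rate)
            for role, by_source in block["hourly_cost"].items()
            for source, rate in by_source.items()
        }
    if "unsocial_multiplier" in block:
        kwargs["unsocial_multiplier"] = {
            (shift, daytype): float(m)
            for shift, by_dt in block["unsocial_multiplier"].items()
            for daytype, m in by_dt.items()
        }
    for key in ("excess_bed_day_cost", "currency"):
        if key in block:
            kwargs[key] = block[key]
    return CostParameters(**kwargs)


def _simulator_from_dict(block: dict) -> SimulatorConfig:
    block = dict(block)
    multipliers = block.pop("multipliers", None)
    cfg = _build(SimulatorConfig, block, "simulator")
    if multipliers is not None:
        cfg.multipliers = CareLevelMultipliers(
            hours={str(k): float(v) for k, v in multipliers.get("hours", {}).items()},
            specialing_hours=float(multipliers.get("specialing_hours", 24.0)),
        )
    return cfg


def experiment_config_from_dict(obj: dict) -> ExperimentConfig:
    _check_keys(
        obj,
        ("generator", "simulator", "costs", "effects", "grid", "master_seed"),
        "config root",
    )
    kwargs = {}
    if "generator" in obj:
        gen = dict(obj["generator"])
        if "level_hours" in gen:
            gen["level_hours"] = {str(k): float(v) for k, v in gen["level_hours"].items()}
        kwargs["generator"] = _build(GeneratorConfig, gen, "generator")
    if "simulator" in obj:
        kwargs["simulator"] = _simulator_from_dict(obj["simulator"])
    if "costs" in obj:
        kwargs["costs"] = _costs_from_dict(obj["costs"])
    if "effects" in obj:
        eff = dict(obj["effects"])
        if "rr_death_per_low_day_ci" in eff:
            eff["rr_death_per_low_day_ci"] = tuple(eff["rr_death_per_low_day_ci"])
        kwargs["effects"] = _build(EffectEstimates, eff, "effects")
    grid = obj.get("grid", {})
    _check_keys(
        grid,
        ("plans", "availabilities", "reference_plan", "variants", "sensitivity_availabilities"),
        "grid",
    )
    for key, value in grid.items():
        kwargs[key] = tuple(value) if isinstance(value, list) else value
    if "master_seed" in obj:
        kwargs["master_seed"] = int(obj["master_seed"])
    return ExperimentConfig(**kwargs)


def load_config(path) -> ExperimentConfig:
    """Load an experiment config from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        obj = json.loads(text)
    else:
        obj = yaml.safe_load(text)
    if obj is None:
        obj = {}
    if not isinstance(obj, dict):
        raise ConfigurationError("config root must be a mapping")
    return experiment_config_from_dict(obj)
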