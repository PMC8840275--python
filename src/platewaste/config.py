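"""YAML configuration loading for the simulator.

A config file holds any subset of the scenario, menu, population, waste-
fraction and competitive-food blocks; omitted keys fall back to the
survey-derived defaults.  Invalid values are rejected at load with the
offending field named.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, replace
from pathlib import Path

import yaml

from .menu_gen import ComponentDistribution, MenuConfig
from .population import PopulationConfig
from .simulator import SimulationConfig
from .waste_model import CompetitiveImpactConfig, WasteFractionConfig

__all__ = ["load_config", "config_from_dict", "config_to_dict", "config_hash"]

_SCENARIO_KEYS = (
    "lunch_duration", "pr_unsatisfied", "ef_prob", "repetitions",
    "walking_delay", "seed", "ideal_mode",
)


def _build(cls, base, block: dict, name: str):
    unknown = set(block) - set(base.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown keys in {name!r} config block: {sorted(unknown)}")
    try:
        return replace(base, **block)
    except ValueError as exc:
        raise ValueError(f"invalid {name!r} config: {exc}") from exc


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a SimulationConfig from a (possibly partial) nested dict."""
    data = dict(data or {})
    menu_block = dict(data.pop("menu", {}))
    dists = menu_block.pop("distributions", None)
    menu = _build(MenuConfig, MenuConfig(), {
        k: tuple(v) if isinstance(v, list) else v for k, v in menu_block.items()
    }, "menu")
    if dists:
        merged = dict(menu.distributions)
        for key, spec in dists.items():
            merged[key] = ComponentDistribution(
                family=spec["family"],
                loc=float(spec["loc"]),
                scale=float(spec.get("scale", 0.0)),
                bounds=tuple(spec.get("bounds", (0.0, float("inf")))),
            )
        menu = replace(menu, distributions=merged)

    population = _build(PopulationConfig, PopulationConfig(),
                        data.pop("population", {}), "population")

    waste_block = dict(data.pop("waste_fractions", {}))
    fracs = waste_block.pop("fractions", None)
    waste = _build(WasteFractionConfig, WasteFractionConfig(), waste_block, "waste_fractions")
    if fracs:
        merged = dict(waste.fractions)
        merged.update({k: tuple(v) for k, v in fracs.items()})
        waste = replace(waste, fractions=merged)

    comp_block = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in dict(data.pop("competitive", {})).items()
    }
    competitive = _build(CompetitiveImpactConfig, CompetitiveImpactConfig(),
                         comp_block, "competitive")

    scenario = data.pop("scenario", {})
    unknown = set(data) | (set(scenario) - set(_SCENARIO_KEYS))
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return SimulationConfig(
            menu=menu, population=population, waste_fractions=waste,
            competitive=competitive, **scenario,
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid scenario config: {exc}") from exc


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML file."""
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Serialize a SimulationConfig to a plain nested dict."""
    return asdict(cfg)


def config_hash(cfg: SimulationConfig) -> str:
    """Stable short hash of the full configuration, for output headers."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
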