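"""Scenario registry: named condition bundles for the synthetic generators.

A :class:`ScenarioSpec` ties a study condition (genotype x environment) to the
parameters the phenomenological generators need (two-compartment kill
parameters, latent low-GTP weight, bulk growth rate), with a citation string
for every non-default number. The registry ships as package data
(``data/scenarios.yaml``) and is append-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

__all__ = [
    "Genotype",
    "Environment",
    "KillParams",
    "ScenarioSpec",
    "scenario_table",
    "get_scenario",
    "scenario_set",
    "cytometry_shape",
]


@dataclass(frozen=True)
class Genotype:
    """Genetic background flags. All True/absent flags default to wild type."""

    rel: bool = True
    sasB: bool = True
    sasB_F42A: bool = False
    sasA: bool = True
    ppGpp0: bool = False
    gmk_Q110R: bool = False
    guaB_down: bool = False


@dataclass(frozen=True)
class Environment:
    carbon_source: str = "glucose_caa"
    inducer: str = "none"  # none|RHX|stationary|CCCP|arsenate|sublethal_bacitracin
    antibiotic: str = "vancomycin"
    serial_passage: int = 0


@dataclass(frozen=True)
class KillParams:
    f: float       # persister plateau fraction
    k_s: float     # susceptible kill rate, 1/h
    k_p: float     # persister kill rate, 1/h
    N0: float      # initial CFU/ml

    def __post_init__(self) -> None:
        if not (0.0 < self.f < 1.0):
            raise ValueError(f"persister fraction f={self.f} must lie in (0, 1)")
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")
        if not (0.0 <= self.k_p < self.k_s):
            raise ValueError(f"require 0 <= k_p < k_s, got k_p={self.k_p}, k_s={self.k_s}")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    genotype: Genotype
    environment: Environment
    kill_params: KillParams
    low_gtp_fraction: float
    growth_rate_per_h: float
    mic_multiple: float
    citation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_gtp_fraction <= 1.0):
            raise ValueError("low_gtp_fraction must lie in [0, 1]")


def _load_registry() -> dict[str, Any]:
    with resources.files("persisterkit.data").joinpath("scenarios.yaml").open() as fh:
        return yaml.safe_load(fh)


_REGISTRY: dict[str, Any] | None = None


def _registry() -> dict[str, Any]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return _REGISTRY


def _build(name: str, raw: dict[str, Any], defaults: dict[str, Any]) -> ScenarioSpec:
    kp = dict(raw["kill_params"])
    kp.setdefault("k_p", defaults["k_p"])
    kp.setdefault("N0", defaults["N0"])
    return ScenarioSpec(
        name=name,
        genotype=Genotype(**raw.get("genotype", {})),
        environment=Environment(**raw.get("environment", {})),
        kill_params=KillParams(**kp),
        low_gtp_fraction=float(raw["low_gtp_fraction"]),
        growth_rate_per_h=float(raw["growth_rate_per_h"]),
        mic_multiple=float(raw.get("mic_multiple", defaults["mic_multiple"])),
        citation=dict(raw.get("citation", {})),
    )


def scenario_table() -> dict[str, ScenarioSpec]:
    """Return the built-in scenario registry, keyed by scenario name."""
    reg = _registry()
    defaults = reg["defaults"]
    return {name: _build(name, raw, defaults) for name, raw in reg["scenarios"].items()}


def get_scenario(name: str) -> ScenarioSpec:
    table = scenario_table()
    try:
        return table[name]
    except KeyError:
        known = ", ".join(sorted(table))
        raise KeyError(f"unknown scenario {name!r}; known scenarios: {known}") from None


def scenario_set(set_name: str) -> list[ScenarioSpec]:
    """Resolve a named scenario group (e.g. ``carbon_sources``) to specs."""
    reg = _registry()
    try:
        names = reg["scenario_sets"][set_name]
    except KeyError:
        known = ", ".join(sorted(reg["scenario_sets"]))
        raise KeyError(f"unknown scenario set {set_name!r}; known sets: {known}") from None
    return [get_scenario(n) for n in names]


def cytometry_shape() -> dict[str, float]:
    """Mixture-shape constants for the cytometry event generator."""
    return dict(_registry()["cytometry"])
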