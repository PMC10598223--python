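"""YAML configuration loading for scenario runs.

A run configuration is a single YAML document with optional blocks::

    phases:
      fluid: {rho: 997.1, cp: 4179, k: 0.613, mu: 1.003e-3, sigma: 0.05}
      solid: {rho: 8933, cp: 385, k: 400, sigma: 5.96e7}
      phi: 0.01
      forms: {conductivity: maxwell_garnett, electrical: maxwell}
    model:  {n: 0.5, M: 0.5, epsilon: 0.01, f_w: 1.0, a: 0.1, Pr: 6.2}
    flags:  {energy_sign: corrected, wall_bc_sign: corrected,
             energy_diffusivity_weight: f_second_power}
    solver: {eta_max: 10, tol: 1.0e-8, delta_reg: 1.0e-8, seed: 0}
    scenarios:
      - {name: m_sweep, sweep: {parameter: M, values: [0, 0.5, 1]},
         permeability_case: suction, overrides: {f_w: 1.0}}

Every violation raises :class:`ConfigError` carrying the offending field
path.  Omitted blocks fall back to package defaults (water/copper phases at
phi = 1%, corrected formulation).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .mixture import PhaseProperties, build_ratios, water_copper_phases
from .model import FormulationFlags, ModelParams
from .scenarios import Scenario, ScenarioError
from .solver import SolverSettings

__all__ = ["ConfigError", "load_config", "RunConfig"]


class ConfigError(ValueError):
    """Configuration schema violation; message includes the field path."""


def _require_mapping(obj, path: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(obj).__name__}")
    return obj


def _phases_from(block: dict) -> tuple[PhaseProperties, str, str]:
    fluid = _require_mapping(block.get("fluid"), "phases.fluid")
    solid = _require_mapping(block.get("solid"), "phases.solid")
    defaults = water_copper_phases(phi=float(block.get("phi", 0.01)))
    try:
        props = PhaseProperties(
            rho_f=float(fluid.get("rho", defaults.rho_f)),
            cp_f=float(fluid.get("cp", defaults.cp_f)),
            k_f=float(fluid.get("k", defaults.k_f)),
            mu_f=float(fluid.get("mu", defaults.mu_f)),
            sigma_f=float(fluid.get("sigma", defaults.sigma_f)),
            rho_s=float(solid.get("rho", defaults.rho_s)),
            cp_s=float(solid.get("cp", defaults.cp_s)),
            k_s=float(solid.get("k", defaults.k_s)),
            sigma_s=float(solid.get("sigma", defaults.sigma_s)),
            phi=defaults.phi,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"phases: {exc}") from exc
    forms = _require_mapping(block.get("forms"), "phases.forms")
    return (props,
            str(forms.get("conductivity", "maxwell_garnett")),
            str(forms.get("electrical", "maxwell")))


def _build(cls, block: dict, path: str, **extra):
    try:
        return cls(**{**{k: v for k, v in block.items()}, **extra})
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


class RunConfig:
    """Fully-resolved run configuration."""

    def __init__(self, phases, model_params, settings, scenarios, raw):
        self.phases = phases
        self.model_params = model_params
        self.settings = settings
        self.scenarios = scenarios
        self.raw = raw


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}") from exc
    doc = _require_mapping(doc, "<document>")

    props, cond_form, elec_form = _phases_from(
        _require_mapping(doc.get("phases"), "phases"))
    try:
        ratios = build_ratios(props, conductivity_form=cond_form,
                              electrical_form=elec_form)
    except ValueError as exc:
        raise ConfigError(f"phases.forms: {exc}") from exc

    flags = _build(FormulationFlags,
                   _require_mapping(doc.get("flags"), "flags"), "flags")
    model_block = _require_mapping(doc.get("model"), "model")
    model_block.setdefault("n", 0.5)
    params = _build(ModelParams, model_block, "model",
                    ratios=ratios, flags=flags)
    settings = _build(SolverSettings,
                      _require_mapping(doc.get("solver"), "solver"), "solver")

    scenarios = []
    for i, sc in enumerate(doc.get("scenarios") or []):
        sc = _require_mapping(sc, f"scenarios[{i}]")
        sweep = _require_mapping(sc.get("sweep"), f"scenarios[{i}].sweep")
        if "parameter" not in sweep:
            raise ConfigError(f"scenarios[{i}].sweep.parameter: required")
        overrides = _require_mapping(sc.get("overrides"),
                                     f"scenarios[{i}].overrides")
        try:
            base = params.replace(**overrides)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"scenarios[{i}].overrides: {exc}") from exc
        try:
            scenarios.append(Scenario(
                name=str(sc.get("name", f"scenario_{i}")),
                base=base,
                sweep_parameter=str(sweep["parameter"]),
                sweep_values=tuple(sweep.get("values", ())),
                permeability_case=str(sc.get("permeability_case",
                                             "impermeable")),
            ))
        except ScenarioError as exc:
            raise ConfigError(f"scenarios[{i}]: {exc}") from exc
    return RunConfig(props, params, settings, scenarios, doc)
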