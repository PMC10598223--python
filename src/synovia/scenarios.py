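"""Parameter-sweep scenarios and golden-fixture generation.

A :class:`Scenario` is one figure-family of the study: a base parameter set,
one swept parameter (n, M, epsilon, a, f_w or phi) and a permeability case
(suction f_w > 0, injection f_w < 0, impermeable f_w = 0).  Running a
scenario produces a tidy table of wall quantities per sweep value; a row
records its own failure rather than aborting the sweep.

Default sweep values follow the stated figure settings where given
(epsilon = 0.01, a = 0.1, phi = 1%, Pr = 6.2) and representative grids
elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .mixture import build_ratios, water_copper_phases
from .model import ModelParams
from .solver import ConvergenceError, SolverSettings, solve

__all__ = [
    "Scenario",
    "ScenarioError",
    "run_scenario",
    "default_scenarios",
    "generate_fixtures",
    "FIXTURE_CASES",
]

SWEEPABLE = ("n", "M", "epsilon", "a", "f_w", "phi")
PERMEABILITY_CASES = ("suction", "injection", "impermeable")


class ScenarioError(ValueError):
    """Scenario configuration error, with the offending field in the message."""


@dataclass(frozen=True)
class Scenario:
    """One parameter sweep over a family of similarity problems."""

    name: str
    base: ModelParams
    sweep_parameter: str
    sweep_values: tuple = ()
    permeability_case: str = "impermeable"
    outputs: tuple = ("wall",)

    def __post_init__(self) -> None:
        if self.sweep_parameter not in SWEEPABLE:
            raise ScenarioError(
                f"{self.name}.sweep_parameter: must be one of {SWEEPABLE}, "
                f"got {self.sweep_parameter!r}")
        if self.permeability_case not in PERMEABILITY_CASES:
            raise ScenarioError(
                f"{self.name}.permeability_case: must be one of "
                f"{PERMEABILITY_CASES}, got {self.permeability_case!r}")
        fw = self.base.f_w
        ok = {"suction": fw > 0, "injection": fw < 0, "impermeable": fw == 0}
        if self.sweep_parameter != "f_w" and not ok[self.permeability_case]:
            raise ScenarioError(
                f"{self.name}.base.f_w: sign {fw} inconsistent with "
                f"permeability case {self.permeability_case!r}")
        object.__setattr__(self, "sweep_values", tuple(self.sweep_values))
        object.__setattr__(self, "outputs", tuple(self.outputs))


def _params_for(base: ModelParams, parameter: str, value: float) -> ModelParams:
    if parameter == "phi":
        ratios = build_ratios(water_copper_phases(phi=value))
        return base.replace(ratios=ratios)
    return base.replace(**{parameter: value})


def run_scenario(s: Scenario,
                 settings: SolverSettings = SolverSettings(),
                 profile_dir: Optional[Path] = None) -> pd.DataFrame:
    """Solve the scenario's sweep; one row per sweep value, in given order.

    Failures are recorded in the ``converged``/``error`` columns; profile
    CSVs are written per run when ``profile_dir`` is given.
    """
    from .solver import save_solution

    rows = []
    for value in s.sweep_values:
        row = {"scenario": s.name, s.sweep_parameter: value}
        try:
            params = _params_for(s.base, s.sweep_parameter, value)
            sol = solve(params, settings)
        except (ConvergenceError, ValueError) as exc:
            row.update(converged=False, error=str(exc))
        else:
            w = sol.wall
            row.update(
                fpp0=w.fpp0, theta0=w.theta0, thetap0=w.thetap0,
                cf_group=w.cf_group, nu_group=w.nu_group,
                delta99=w.delta99, deltaT99=w.deltaT99,
                converged=True, error="",
                max_residual=sol.diagnostics["max_residual"],
                eta_max_used=sol.diagnostics["eta_max_used"],
                n_nodes=sol.diagnostics["n_nodes"],
            )
            if profile_dir is not None:
                profile_dir = Path(profile_dir)
                profile_dir.mkdir(parents=True, exist_ok=True)
                stem = f"{s.name}_{s.sweep_parameter}={value:g}"
                save_solution(sol, profile_dir / f"{stem}.csv")
        rows.append(row)
    columns = ["scenario", s.sweep_parameter, "fpp0", "theta0", "thetap0",
               "cf_group", "nu_group", "delta99", "deltaT99", "converged",
               "error", "max_residual", "eta_max_used", "n_nodes"]
    return pd.DataFrame(rows, columns=columns)


def default_scenarios(phi: float = 0.01) -> list[Scenario]:
    """Packaged sweep families mirroring the study's figure structure.

    {n, M, epsilon, a} sweeps for each of the suction / injection /
    impermeable cases, at the caption defaults epsilon = 0.01, a = 0.1,
    phi = 1%, Pr = 6.2, with a pseudo-plastic base (n = 0.5).
    """
    ratios = build_ratios(water_copper_phases(phi=phi))
    cases = {"suction": 1.0, "injection": -0.5, "impermeable": 0.0}
    sweeps = {
        "n": (0.25, 0.5, 0.75, 1.0),
        "M": (0.0, 0.5, 1.0, 2.0),
        "epsilon": (0.0, 0.01, 0.05, 0.1),
        "a": (0.01, 0.1, 1.0, 10.0),
    }
    scenarios = []
    for case, fw in cases.items():
        base = ModelParams(n=0.5, M=0.0, epsilon=0.01, f_w=fw, a=0.1,
                           Pr=6.2, ratios=ratios)
        for parameter, values in sweeps.items():
            scenarios.append(Scenario(
                name=f"{parameter}_sweep_{case}", base=base,
                sweep_parameter=parameter, sweep_values=values,
                permeability_case=case))
    return scenarios


def _fixture_cases() -> dict[str, tuple[ModelParams, SolverSettings]]:
    phi1 = build_ratios(water_copper_phases(phi=0.01))
    base_settings = SolverSettings()
    return {
        # Newtonian flat plate: momentum reduces to the Blasius problem
        "blasius": (
            ModelParams(n=1.0, M=0.0, epsilon=0.0, f_w=0.0, a=0.1, Pr=6.2),
            base_settings),
        # shear-thinning suction with magnetic field (domain continuation)
        "pseudoplastic_suction": (
            ModelParams(n=0.5, M=0.5, epsilon=0.0, f_w=1.0, a=0.1, Pr=6.2,
                        ratios=phi1),
            base_settings),
        # Newtonian injection under a strong field
        "newtonian_injection_mhd": (
            ModelParams(n=1.0, M=1.0, epsilon=0.0, f_w=-0.5, a=0.1, Pr=6.2),
            base_settings),
        # reference case with weak stagnation straining: eps^2 never decays,
        # so this one is solved on the fixed default domain
        "pseudoplastic_suction_stagnation": (
            ModelParams(n=0.5, M=0.5, epsilon=0.01, f_w=1.0, a=0.1, Pr=6.2,
                        ratios=phi1),
            base_settings),
    }


#: Names of the golden fixture cases (regeneration must be diff-clean).
FIXTURE_CASES = tuple(_fixture_cases())


def generate_fixtures(out_dir, settings: Optional[SolverSettings] = None,
                      cases: Optional[Sequence[str]] = None) -> dict[str, dict]:
    """(Re)generate the golden wall-value fixtures; deterministic.

    Writes one JSON file per case under ``out_dir`` and returns the payloads;
    ``cases`` restricts regeneration to a subset of :data:`FIXTURE_CASES`.
    Any non-convergent case is a hard failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payloads = {}
    for name, (params, case_settings) in _fixture_cases().items():
        if cases is not None and name not in cases:
            continue
        if settings is not None:
            case_settings = settings
        sol = solve(params, case_settings)
        payload = {
            "name": name,
            "params": asdict(params),
            "settings": asdict(case_settings),
            "wall": asdict(sol.wall),
            "diagnostics": sol.diagnostics,
        }
        (out_dir / f"{name}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        payloads[name] = payload
    return payloads
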