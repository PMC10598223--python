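"""Shared solved cases; session-scoped because each BVP solve is nontrivial."""

import pytest

from synovia import ModelParams, SolverSettings, build_ratios, solve, water_copper_phases


@pytest.fixture(scope="session")
def ratios_phi1():
    """Water/copper mixture ratios at 1% volume fraction."""
    return build_ratios(water_copper_phases(phi=0.01))


@pytest.fixture(scope="session")
def blasius_params():
    return ModelParams(n=1.0, M=0.0, epsilon=0.0, f_w=0.0, a=0.1, Pr=6.2)


@pytest.fixture(scope="session")
def blasius_solution(blasius_params):
    """Newtonian flat plate: momentum reduces to f''' + f f''/2 = 0."""
    return solve(blasius_params)


@pytest.fixture(scope="session")
def reference_params(ratios_phi1):
    """Shear-thinning suction case with magnetic field and weak straining."""
    return ModelParams(n=0.5, M=0.5, epsilon=0.01, f_w=1.0, a=0.1, Pr=6.2,
                       ratios=ratios_phi1)


@pytest.fixture(scope="session")
def reference_solution(reference_params):
    return solve(reference_params)


@pytest.fixture(scope="session")
def adiabatic_solution():
    """a = 0: insulated wall, the temperature field is identically zero."""
    return solve(ModelParams(n=0.5, M=0.5, epsilon=0.0, f_w=1.0, a=0.0,
                             Pr=6.2))


@pytest.fixture(scope="session")
def default_settings():
    return SolverSettings()
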