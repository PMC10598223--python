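"""Reduced ODE system: symbolic limits, hand-evaluated residuals, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from synovia.mixture import MixtureRatios
from synovia.model import (FormulationFlags, ModelParams, State,
                           boundary_residuals, diffusivity_weight,
                           energy_residual, momentum_residual,
                           regularized_shear_from_g, shear_from_g,
                           to_first_order, wall_thermal_residual)

NEWTONIAN = ModelParams(n=1.0, M=0.0, epsilon=0.0, f_w=0.0, a=0.1, Pr=6.2)

state_st = st.builds(
    State,
    f=st.floats(-2, 5),
    fp=st.floats(0, 1.5),
    g=st.floats(-2, 2),
    theta=st.floats(0, 1),
    q=st.floats(-1, 1),
)


class TestShearVariable:
    def test_identity_at_n_equal_one(self):
        g = np.linspace(-2, 2, 11)
        assert np.allclose(shear_from_g(g, 1.0), g)
        assert np.allclose(regularized_shear_from_g(g, 1.0, 1e-8), g)

    @pytest.mark.parametrize("n", [0.25, 0.5, 1.5])
    def test_regularized_matches_exact_away_from_zero(self, n):
        g = np.array([-1.5, -0.1, 0.1, 1.5])
        exact = shear_from_g(g, n)
        reg = regularized_shear_from_g(g, n, 1e-8)
        assert np.allclose(reg, exact, rtol=1e-6)

    def test_same_sign_as_g(self):
        for n in (0.5, 1.0, 1.5):
            assert shear_from_g(-0.3, n) < 0 < shear_from_g(0.3, n)


class TestMomentumResidual:
    def test_blasius_reduction(self):
        # n=1, unit ratios, M=0, eps=0: g' must equal -f f''/2 exactly
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = State(f=rng.uniform(-1, 3), fp=rng.uniform(0, 1.2),
                      g=rng.uniform(-1, 1), theta=0.0, q=0.0)
            assert momentum_residual(s, NEWTONIAN) == pytest.approx(
                -0.5 * s.f * s.g, abs=1e-12)

    def test_free_stream_equilibrium(self):
        s = State(f=3.0, fp=1.0, g=0.0, theta=0.0, q=0.0)
        for n in (0.5, 1.0, 1.5):
            for M in (0.0, 2.0):
                p = ModelParams(n=n, M=M, epsilon=0.0)
                assert momentum_residual(s, p) == 0.0

    def test_hand_evaluated_value(self):
        # n=0.5, f=1, f'=0.5, f''=0.2, M=0.1, eps=0.01, unit ratios:
        # g' = -(1/1.5)(0.2) + 0.01(-0.5) + 0.0001
        p = ModelParams(n=0.5, M=0.1, epsilon=0.01)
        s = State(f=1.0, fp=0.5, g=0.2**0.5, theta=0.0, q=0.0)
        assert momentum_residual(s, p) == pytest.approx(
            -0.13823333333333335, rel=1e-12)


class TestEnergyResidual:
    def test_classical_flat_plate_reduction(self):
        # n=1, unit ratios, corrected: q' = -(Pr/2) f theta'
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = State(f=rng.uniform(-1, 3), fp=0.5, g=0.4, theta=0.5,
                      q=rng.uniform(-1, 0))
            assert energy_residual(s, NEWTONIAN) == pytest.approx(
                -0.5 * 6.2 * s.f * s.q, abs=1e-12)

    def test_stagnant_fluid_freezes_flux(self):
        s = State(f=0.0, fp=0.0, g=0.3, theta=0.8, q=-0.2)
        for n in (0.5, 1.0):
            assert energy_residual(s, ModelParams(n=n)) == 0.0

    def test_hand_evaluated_value(self):
        # n=0.5, Pr=6.2, f=1, theta'=-0.3, f''=0.2: q' = -(6.2/1.5)(1)(-0.3)
        p = ModelParams(n=0.5, Pr=6.2)
        fpp = 0.2
        q = -0.3 * fpp ** (0.5 - 1.0)   # q = theta' |f''|^(n-1)
        s = State(f=1.0, fp=0.5, g=fpp**0.5, theta=0.5, q=q)
        assert energy_residual(s, p) == pytest.approx(1.2399999999999998,
                                                      rel=1e-12)

    def test_as_printed_flips_sign(self):
        s = State(f=1.0, fp=0.5, g=0.4, theta=0.5, q=-0.2)
        printed = ModelParams(n=1.0, flags=FormulationFlags(
            energy_sign="as_printed"))
        assert energy_residual(s, printed) == pytest.approx(
            -energy_residual(s, NEWTONIAN), rel=1e-14)


class TestBoundaryResiduals:
    def test_adiabatic_limit(self):
        p = ModelParams(n=1.0, a=0.0)
        assert wall_thermal_residual(0.7, 0.0, p) == 0.0

    def test_suction_offset(self):
        p = ModelParams(n=1.0, f_w=1.0)
        left = State(f=0.0, fp=0.0, g=0.3, theta=0.1, q=-0.05)
        right = State(f=9.0, fp=1.0, g=0.0, theta=0.0, q=0.0)
        res = boundary_residuals(left, right, p)
        assert res[0] == pytest.approx(-1.0)

    def test_wall_bc_sign_conventions(self):
        corrected = ModelParams(n=1.0, a=0.5,
                                ratios=MixtureRatios.unity())
        printed = corrected.replace(flags=FormulationFlags(
            wall_bc_sign="as_printed"))
        theta0 = 0.2
        # corrected: theta'(0) = -(a/A3)(1-theta0) zeroes the residual
        assert wall_thermal_residual(theta0, -0.5 * 0.8, corrected) \
            == pytest.approx(0.0, abs=1e-15)
        # as printed: theta'(0) = +A3 a (1-theta0) zeroes it instead
        assert wall_thermal_residual(theta0, 0.5 * 0.8, printed) \
            == pytest.approx(0.0, abs=1e-15)

    def test_converged_solution_residuals_vanish(self, blasius_solution):
        sol = blasius_solution
        left = State(sol.f[0], sol.fp[0],
                     shear_from_g(sol.fpp[0], 1.0), sol.theta[0],
                     sol.thetap[0])
        right = State(sol.f[-1], sol.fp[-1], sol.fpp[-1], sol.theta[-1],
                      sol.thetap[-1])
        res = boundary_residuals(left, right, sol.params)
        assert np.max(np.abs(res)) < 1e-6


class TestAssembledSystem:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(s=state_st)
    def test_newtonian_limit_matches_blasius_energy_system(self, s):
        rhs = to_first_order(NEWTONIAN)
        got = rhs(0.0, np.array(s))
        expected = np.array([
            s.fp, s.g, -0.5 * s.f * s.g, s.q, -0.5 * 6.2 * s.f * s.q])
        assert np.allclose(got, expected, atol=1e-12)

    def test_free_stream_fixed_point(self):
        for n in (0.5, 1.0, 1.5):
            for M in (0.0, 1.0):
                rhs = to_first_order(ModelParams(n=n, M=M, epsilon=0.0))
                d = rhs(0.0, np.array([4.0, 1.0, 0.0, 0.0, 0.0]))
                # f keeps growing linearly; everything else is stationary
                assert d[0] == 1.0
                assert np.allclose(d[1:], 0.0, atol=1e-12)

    @pytest.mark.parametrize("n", [0.5, 1.0])
    def test_rhs_matches_trajectory_derivative(self, n):
        # integrate the assembled RHS, then check its own trajectory
        # differentiates back onto it (second-order central differences)
        p = ModelParams(n=n, M=0.3, epsilon=0.01, f_w=0.5, a=0.2)
        rhs = to_first_order(p)
        y0 = np.array([0.5, 0.0, 0.33, 0.2, -0.1])
        ivp = solve_ivp(rhs, (0.0, 2.0), y0, method="DOP853", rtol=1e-12,
                        atol=1e-12, dense_output=True)
        eta0, h = 1.0, 1e-4
        fd = (ivp.sol(eta0 + h) - ivp.sol(eta0 - h)) / (2 * h)
        assert np.allclose(fd, rhs(eta0, ivp.sol(eta0)), atol=1e-6)

    def test_vectorized_evaluation(self):
        rhs = to_first_order(ModelParams(n=0.5))
        y = np.random.default_rng(3).uniform(0.1, 1.0, size=(5, 7))
        out = rhs(np.linspace(0, 1, 7), y)
        assert out.shape == (5, 7)
        cols = np.stack([rhs(0.0, y[:, j]) for j in range(7)], axis=1)
        assert np.allclose(out, cols)


class TestParameterValidation:
    def test_invalid_rejected(self):
        for kwargs in ({"n": 0.0}, {"n": 1.0, "M": -1.0},
                       {"n": 1.0, "Pr": 0.0}, {"n": 1.0, "a": -0.1},
                       {"n": 1.0, "epsilon": -0.5}):
            with pytest.raises(ValueError):
                ModelParams(**kwargs)
        with pytest.raises(ValueError):
            FormulationFlags(energy_sign="sideways")

    def test_weight_conversion(self):
        assert diffusivity_weight(0.2, 0.5) == pytest.approx(0.2**0.5)
        assert diffusivity_weight(0.0, 0.5, delta_reg=1e-8) == pytest.approx(
            1e-4)
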