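"""Wall groups, thicknesses, dimensional reconstruction and identities."""

import numpy as np
import pytest

from synovia.postprocess import (dimensionalize, heat_transfer_coefficient,
                                 reynolds_number,
                                 similarity_groups_from_dimensional,
                                 transpiration_velocity, velocity_at,
                                 wall_quantities, wall_stress_and_flux)
from synovia.solver import Solution

FLOW = dict(U_inf=0.01, nu_f=1e-6, rho_f=997.1, k_f=0.613,
            T_f=310.0, T_inf=305.0)


class TestWallQuantities:
    def test_newtonian_friction_group(self, blasius_solution):
        w = blasius_solution.wall
        # n=1, unit ratios: the group is just -2 f''(0)
        assert w.cf_group == pytest.approx(-2.0 * w.fpp0, rel=1e-13)

    def test_adiabatic_zero_nusselt(self, adiabatic_solution):
        w = adiabatic_solution.wall
        assert w.nu_group == 0.0
        assert w.deltaT99 == 0.0

    def test_thicknesses_within_domain(self, reference_solution):
        w = reference_solution.wall
        eta_max = reference_solution.diagnostics["eta_max_used"]
        assert 0 < w.deltaT99 < w.delta99 <= eta_max
        # delta99 really is the 99% point of the velocity profile
        fp_at = np.interp(w.delta99, reference_solution.eta,
                          reference_solution.fp)
        assert fp_at == pytest.approx(0.99, abs=1e-6)

    def test_refuses_unconverged(self, blasius_solution):
        broken = Solution(
            eta=blasius_solution.eta, f=blasius_solution.f,
            fp=blasius_solution.fp, fpp=blasius_solution.fpp,
            theta=blasius_solution.theta, thetap=blasius_solution.thetap,
            params=blasius_solution.params,
            settings=blasius_solution.settings,
            diagnostics={"converged": False})
        with pytest.raises(ValueError):
            wall_quantities(broken)


class TestTranspiration:
    def test_impermeable_wall(self):
        assert transpiration_velocity(0.3, 0.5, 0.01, 1e-6, 0.0) == 0.0

    def test_newtonian_closed_form(self):
        x, U, nu, fw = 0.2, 0.05, 1e-6, 0.7
        expected = -0.5 * np.sqrt(nu * U / x) * fw
        assert transpiration_velocity(x, 1.0, U, nu, fw) == pytest.approx(
            expected, rel=1e-14)

    def test_shear_thinning_value(self):
        # n=0.5, nu=1e-6, U=0.01, x=0.1, f_w=1
        assert transpiration_velocity(0.1, 0.5, 0.01, 1e-6, 1.0) == \
            pytest.approx(-0.00014362897933545897, rel=1e-13)

    def test_suction_points_into_wall(self):
        assert transpiration_velocity(0.1, 0.5, 0.01, 1e-6, 1.0) < 0
        assert transpiration_velocity(0.1, 0.5, 0.01, 1e-6, -1.0) > 0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            transpiration_velocity(0.0, 0.5, 0.01, 1e-6, 1.0)


class TestHeatTransferCoefficient:
    @pytest.mark.parametrize("x, c, n, expected", [
        (4.0, 0.0, 0.5, 0.0),
        (4.0, 2.0, 1.0, 1.0),       # c x^(-1/2)
        (9.0, 6.0, 1.0, 2.0),
    ])
    def test_values(self, x, c, n, expected):
        assert heat_transfer_coefficient(x, c, n) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            heat_transfer_coefficient(-1.0, 1.0, 0.5)


class TestDimensionalField:
    def test_adiabatic_temperature_uniform(self, adiabatic_solution):
        fld = dimensionalize(adiabatic_solution, x=0.5, **{
            k: FLOW[k] for k in ("U_inf", "nu_f", "T_f", "T_inf")})
        assert np.allclose(fld.T, FLOW["T_inf"])

    def test_velocity_limits(self, blasius_solution):
        fld = dimensionalize(blasius_solution, x=[0.2, 0.5], **{
            k: FLOW[k] for k in ("U_inf", "nu_f", "T_f", "T_inf")})
        assert np.allclose(fld.u[:, 0], 0.0)
        assert np.allclose(fld.u[:, -1], FLOW["U_inf"], rtol=1e-6)
        assert fld.y.shape == fld.u.shape == fld.v.shape == fld.T.shape

    def test_wall_trace_matches_transpiration(self, reference_solution):
        x = np.array([0.2, 0.6, 1.1])
        fld = dimensionalize(reference_solution, x=x, **{
            k: FLOW[k] for k in ("U_inf", "nu_f", "T_f", "T_inf")})
        assert np.allclose(fld.v[:, 0], fld.Vw, rtol=1e-10)
        expected = transpiration_velocity(
            x, reference_solution.params.n, FLOW["U_inf"], FLOW["nu_f"],
            reference_solution.params.f_w)
        assert np.allclose(fld.Vw, expected, rtol=1e-12)

    def test_singular_station_rejected(self, blasius_solution):
        with pytest.raises(ValueError):
            dimensionalize(blasius_solution, x=0.0, U_inf=0.01, nu_f=1e-6,
                           T_f=310.0, T_inf=305.0)

    def test_continuity_residual_refines_at_second_order(self,
                                                         blasius_solution):
        # central-difference div(u, v) on a patch, two step sizes: the
        # residual must shrink ~4x per halving (the field is exact in the
        # similarity sense, so only discretization error remains)
        U, nu = FLOW["U_inf"], FLOW["nu_f"]
        x0 = np.linspace(0.4, 0.6, 21)
        yscale = np.sqrt(nu * 0.5 / U)
        y0 = np.linspace(0.5, 4.0, 21) * yscale

        def max_div(hx, hy):
            X, Y = np.meshgrid(x0, y0, indexing="ij")
            dudx = (velocity_at(blasius_solution, X + hx, Y, U, nu)[0]
                    - velocity_at(blasius_solution, X - hx, Y, U, nu)[0]) / (2 * hx)
            dvdy = (velocity_at(blasius_solution, X, Y + hy, U, nu)[1]
                    - velocity_at(blasius_solution, X, Y - hy, U, nu)[1]) / (2 * hy)
            return float(np.max(np.abs(dudx + dvdy)))

        hx, hy = 1e-3, 1e-3 * yscale
        r1 = max_div(hx, hy)
        r2 = max_div(hx / 2, hy / 2)
        scale = U / 0.5                      # magnitude of the du/dx terms
        assert r1 < 1e-4 * scale
        assert r1 / r2 == pytest.approx(4.0, rel=0.35)


class TestDimensionalIdentities:
    def test_adiabatic_wall_flux_zero(self, adiabatic_solution):
        _, q_w = wall_stress_and_flux(adiabatic_solution, 0.5, **FLOW)
        assert q_w == 0.0

    @pytest.mark.parametrize("x", [0.05, 0.5, 2.0])
    def test_similarity_round_trip(self, reference_solution, x):
        cf, nu = similarity_groups_from_dimensional(reference_solution, x,
                                                    **FLOW)
        w = reference_solution.wall
        assert cf == pytest.approx(w.cf_group, rel=1e-10)
        assert nu == pytest.approx(w.nu_group, rel=1e-10)

    def test_reynolds_newtonian_reduction(self):
        assert reynolds_number(2.0, 0.1, 1e-6) == pytest.approx(2e5)
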