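"""Wall quantities, boundary-layer thicknesses and dimensional fields.

The engineering outputs of the similarity solution are the reduced
skin-friction and Nusselt groups

    Cf_x Re_x^(1/(n+1))  = -2 (mu_bf/mu_f) f''(0) |f''(0)|^(n-1),
    Nu_x Re_x^(-1/(n+1)) = -(k_bf/k_f) theta'(0),

together with the 99% velocity thickness delta99 (f' = 0.99) and a thermal
thickness deltaT99 defined here as the point where theta has decayed to 1%
of its wall value.  The local Reynolds number is never needed on its own by
these groups; for the dimensional round-trip checks it is taken as
``Re_x = U_inf^(2-n) x^n / nu_f`` — the combination appearing inside the
similarity variable.  The sign convention of the friction group (leading
-2, so positive wall shear gives a negative group) is kept as defined.

Dimensional reconstruction inverts the similarity map:

    u = U_inf f'(eta),                y = eta (nu_f x / U_inf^(2-n))^(1/(n+1)),
    v = -(1/(n+1)) (U_inf^(2n-1) nu_f / x^n)^(1/(n+1)) (f - eta f'),
    T = T_inf + theta (T_f - T_inf),

whose wall trace reproduces the transpiration velocity
``V_w(x) = -(1/(n+1)) (nu_f U_inf^(2n-1)/x^n)^(1/(n+1)) f_w`` (suction
``f_w > 0`` gives an inward, negative wall-normal velocity).  The convective
heat-transfer coefficient scales as ``h_f = c x^(-1/(n+1))``, which is what
renders the conjugate parameter ``a`` independent of x.  In the Nusselt
definition the driving temperature difference ``T_f - T_inf`` of the heating
fluid is used, which is the choice under which the dimensional
coefficients reproduce the similarity groups identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mixture import MixtureRatios
from .solver import Solution

__all__ = [
    "WallQuantities",
    "DimensionalField",
    "wall_quantities",
    "dimensionalize",
    "transpiration_velocity",
    "heat_transfer_coefficient",
    "wall_stress_and_flux",
    "similarity_groups_from_dimensional",
    "reynolds_number",
]


@dataclass(frozen=True)
class WallQuantities:
    """Wall values and derived dimensionless groups of a solution."""

    fpp0: float
    theta0: float
    thetap0: float
    cf_group: float    # Cf_x * Re_x^(1/(n+1))
    nu_group: float    # Nu_x * Re_x^(-1/(n+1))
    delta99: float     # velocity boundary-layer thickness (eta units)
    deltaT99: float    # thermal boundary-layer thickness (eta units)


@dataclass(frozen=True)
class DimensionalField:
    """Dimensional velocity/temperature field on an (x, eta) product grid.

    2-D arrays are indexed ``[i, j]`` by streamwise station ``x[i]`` and
    similarity node ``eta[j]``; ``y[i, j]`` is the physical wall distance of
    that node.  ``Vw`` and ``hf`` are per-station wall values.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    T: np.ndarray
    Vw: np.ndarray
    hf: np.ndarray


def _crossing(eta: np.ndarray, values: np.ndarray, level: float,
              rising: bool) -> float:
    """First eta where a monotone profile crosses ``level`` (linear interp)."""
    hit = values >= level if rising else values <= level
    if hit[0]:
        return float(eta[0])
    if not hit.any():
        return float(eta[-1])
    j = int(np.argmax(hit))
    x0, x1 = eta[j - 1], eta[j]
    v0, v1 = values[j - 1], values[j]
    if v1 == v0:
        return float(x1)
    return float(x0 + (level - v0) * (x1 - x0) / (v1 - v0))


def wall_quantities(sol: Solution, ratios: Optional[MixtureRatios] = None,
                    n: Optional[float] = None) -> WallQuantities:
    """Evaluate the reduced wall groups of a converged solution.

    Refuses unconverged solutions (the groups would be meaningless).
    """
    if not sol.diagnostics.get("converged", False):
        raise ValueError(
            f"solution is not converged: {sol.diagnostics}")
    if ratios is None:
        ratios = sol.params.ratios
    if n is None:
        n = sol.params.n
    fpp0 = float(sol.fpp[0])
    theta0 = float(sol.theta[0])
    thetap0 = float(sol.thetap[0])
    cf_group = -2.0 * ratios.A1 * fpp0 * abs(fpp0) ** (n - 1.0)
    nu_group = -ratios.A3 * thetap0
    delta99 = _crossing(sol.eta, sol.fp, 0.99, rising=True)
    if theta0 <= 0:
        deltaT99 = 0.0
    else:
        deltaT99 = _crossing(sol.eta, sol.theta, 0.01 * theta0, rising=False)
    return WallQuantities(fpp0=fpp0, theta0=theta0, thetap0=thetap0,
                          cf_group=cf_group, nu_group=nu_group,
                          delta99=delta99, deltaT99=deltaT99)


def reynolds_number(x, U_inf: float, nu_f: float, n: float = 1.0):
    """Generalized local Reynolds number Re_x = U_inf^(2-n) x^n / nu_f."""
    x = np.asarray(x, dtype=float)
    out = U_inf ** (2.0 - n) * x**n / nu_f
    return out if out.ndim else float(out)


def _eta_scale(x, U_inf: float, nu_f: float, n: float):
    """d(eta)/dy = (U_inf^(2-n) / (nu_f x))^(1/(n+1))."""
    return (U_inf ** (2.0 - n) / (nu_f * x)) ** (1.0 / (n + 1.0))


def transpiration_velocity(x, n: float, U_inf: float, nu_f: float,
                           f_w: float):
    """Wall transpiration V_w(x); negative for suction (f_w > 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be > 0")
    out = (-1.0 / (n + 1.0)) * (nu_f * U_inf ** (2.0 * n - 1.0) / x**n) \
        ** (1.0 / (n + 1.0)) * f_w
    return out if out.ndim else float(out)


def heat_transfer_coefficient(x, c_coef: float, n: float):
    """Streamwise decay of the heating coefficient, h_f = c x^(-1/(n+1))."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be > 0")
    if c_coef < 0:
        raise ValueError("c_coef must be >= 0")
    out = c_coef * x ** (-1.0 / (n + 1.0))
    return out if out.ndim else float(out)


def _profiles_at(sol: Solution, eta: np.ndarray):
    """(f, f') at arbitrary eta, extended linearly into the free stream."""
    eta = np.asarray(eta, dtype=float)
    inside = eta <= sol.eta[-1]
    f = np.empty_like(eta)
    fp = np.empty_like(eta)
    theta = np.empty_like(eta)
    if sol.interp is not None:
        y_in = sol.interp(np.clip(eta, 0.0, sol.eta[-1]))
        f_in, fp_in, th_in = y_in[0], y_in[1], y_in[3]
    else:
        f_in = np.interp(np.clip(eta, 0.0, sol.eta[-1]), sol.eta, sol.f)
        fp_in = np.interp(np.clip(eta, 0.0, sol.eta[-1]), sol.eta, sol.fp)
        th_in = np.interp(np.clip(eta, 0.0, sol.eta[-1]), sol.eta, sol.theta)
    f = np.where(inside, f_in, sol.f[-1] + (eta - sol.eta[-1]) * sol.fp[-1])
    fp = np.where(inside, fp_in, sol.fp[-1])
    theta = np.where(inside, th_in, 0.0)
    return f, fp, theta


def dimensionalize(sol: Solution, x, U_inf: float, nu_f: float,
                   T_f: float, T_inf: float,
                   c_coef: float = 0.0) -> DimensionalField:
    """Reconstruct the dimensional (u, v, T) field from the similarity profiles.

    ``x`` may be a scalar or an array of streamwise stations (m); the
    wall-normal grid is the solution's eta mesh mapped to physical y at each
    station.  ``c_coef`` scales the heat-transfer coefficient h_f.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        raise ValueError("x must be > 0 (similarity coordinate is singular)")
    n = sol.params.n
    eta = sol.eta
    f, fp, theta = sol.f, sol.fp, sol.theta

    scale = _eta_scale(x, U_inf, nu_f, n)            # (m,)
    y = eta[None, :] / scale[:, None]
    u = np.broadcast_to(U_inf * fp[None, :], y.shape).copy()
    v_coef = (1.0 / (n + 1.0)) * (U_inf ** (2.0 * n - 1.0) * nu_f / x**n) \
        ** (1.0 / (n + 1.0))                          # (m,)
    v = -v_coef[:, None] * (f - eta * fp)[None, :]
    T = T_inf + theta[None, :] * (T_f - T_inf)
    T = np.broadcast_to(T, y.shape).copy()
    Vw = transpiration_velocity(x, n, U_inf, nu_f, sol.params.f_w)
    hf = heat_transfer_coefficient(x, c_coef, n) if c_coef > 0 \
        else np.zeros_like(x)
    return DimensionalField(x=x, y=y, u=u, v=np.asarray(v), T=T,
                            Vw=np.atleast_1d(Vw), hf=np.atleast_1d(hf))


def velocity_at(sol: Solution, x, y, U_inf: float, nu_f: float):
    """(u, v) at arbitrary physical points; broadcasts x against y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = sol.params.n
    eta = y * _eta_scale(x, U_inf, nu_f, n)
    f, fp, _ = _profiles_at(sol, eta)
    u = U_inf * fp
    v_coef = (1.0 / (n + 1.0)) * (U_inf ** (2.0 * n - 1.0) * nu_f / x**n) \
        ** (1.0 / (n + 1.0))
    v = -v_coef * (f - eta * fp)
    return u, v


def wall_stress_and_flux(sol: Solution, x, U_inf: float, nu_f: float,
                         rho_f: float, k_f: float, T_f: float, T_inf: float):
    """Dimensional wall shear stress and wall heat flux at station(s) x.

    Uses ``mu_f = rho_f nu_f``, ``mu_bf = A1 mu_f`` and ``k_bf = A3 k_f``:

        tau_w = mu_bf (|du/dy|^(n-1) du/dy)_0,   q_w = -k_bf (dT/dy)_0.
    """
    if not sol.diagnostics.get("converged", False):
        raise ValueError("solution is not converged")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be > 0")
    n = sol.params.n
    r = sol.params.ratios
    mu_bf = r.A1 * rho_f * nu_f
    k_bf = r.A3 * k_f
    scale = _eta_scale(x, U_inf, nu_f, n)
    dudy0 = U_inf * sol.fpp[0] * scale
    tau_w = mu_bf * np.abs(dudy0) ** (n - 1.0) * dudy0
    dTdy0 = (T_f - T_inf) * sol.thetap[0] * scale
    q_w = -k_bf * dTdy0
    return tau_w, q_w


def similarity_groups_from_dimensional(sol: Solution, x, U_inf: float,
                                       nu_f: float, rho_f: float, k_f: float,
                                       T_f: float, T_inf: float):
    """Recover (Cf_x Re^(1/(n+1)), Nu_x Re^(-1/(n+1))) dimensionally.

    Internal identity check: the result must match the similarity-space
    groups in :class:`WallQuantities` at every station x.
    """
    n = sol.params.n
    tau_w, q_w = wall_stress_and_flux(sol, x, U_inf, nu_f, rho_f, k_f,
                                      T_f, T_inf)
    Re = reynolds_number(x, U_inf, nu_f, n)
    cf = -2.0 * tau_w / (rho_f * U_inf**2)
    nu = np.asarray(x) * q_w / (k_f * (T_f - T_inf))
    return cf * Re ** (1.0 / (n + 1.0)), nu * Re ** (-1.0 / (n + 1.0))
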