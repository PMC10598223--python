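"""Similarity-reduced boundary-layer equations for a power-law MHD flow.

The dimensional problem is steady, laminar, incompressible two-dimensional
flow of a pseudo-plastic (power-law, index ``n``) base fluid over a flat,
porous, convectively heated articular surface, with a transverse magnetic
field and a weak stagnation-point (free-stream straining) contribution.
With the similarity variable

    eta = (U_inf^(2-n) / (nu_f x))^(1/(n+1)) * y,
    psi = (U_inf^(2n-1) nu_f x)^(1/(n+1)) * f(eta),
    theta = (T - T_inf) / (T_f - T_inf),

the PDEs collapse to the coupled ODE system

    (|f''|^(n-1) f'')' / (A4 A1) + f f'' / (n+1)
        - M^2 (sigma_bf/sigma_f) (f' - 1) - eps^2 = 0,
    (A3/(Pr A2)) (|f''|^(n-1) theta')' + f theta' / (n+1) = 0,

with boundary conditions f(0) = f_w, f'(0) = 0, f'(inf) = 1,
theta'(0) = -(a/A3)(1 - theta(0)) and theta(inf) = 0.  Here ``M`` is the
magnetic parameter, ``eps`` the stagnation parameter, ``f_w`` wall
suction (>0) / injection (<0), ``a`` the convective (conjugate) parameter
and ``Pr`` the base-fluid Prandtl number; ``A1..A4`` and the conductivity
ratio come from :mod:`synovia.mixture`.

The signs of the energy equation and of the wall thermal condition above are
the *corrected* defaults: they are the ones consistent with the dimensional
statements (convection balancing diffusion, and
``-k_bf dT/dy = h_f (T_f - T_w)`` at the wall) and they admit a temperature
field with ``theta(0)`` in (0, 1] decaying to zero.  The literal
``as_printed`` alternatives (flipped energy sign; wall condition
``theta'(0) = A3 a (1 - theta(0))``) are retained behind
:class:`FormulationFlags` for auditability — for n = 1 the printed energy
sign gives ``theta'' = +(Pr/2) f theta'``, which has no decaying solution.

First-order state: ``(f, f', g, theta, q)`` with the shear variable
``g = |f''|^(n-1) f''`` and heat-flux variable ``q = |f''|^(n-1) theta'``
(or ``q = theta'`` when the diffusivity weighting is disabled).  The
``|f''|`` factors are floored at ``delta_reg`` so the right-hand side stays
Lipschitz where f'' crosses zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple

import numpy as np

from .mixture import MixtureRatios

__all__ = [
    "FormulationFlags",
    "ModelParams",
    "State",
    "shear_from_g",
    "regularized_shear_from_g",
    "diffusivity_weight",
    "momentum_residual",
    "energy_residual",
    "boundary_residuals",
    "to_first_order",
]

_SIGN_CHOICES = ("corrected", "as_printed")
_WEIGHT_CHOICES = ("f_second_power", "unweighted")


@dataclass(frozen=True)
class FormulationFlags:
    """Switches between the corrected and literal formulations."""

    energy_sign: str = "corrected"
    wall_bc_sign: str = "corrected"
    energy_diffusivity_weight: str = "f_second_power"

    def __post_init__(self) -> None:
        if self.energy_sign not in _SIGN_CHOICES:
            raise ValueError(f"energy_sign must be one of {_SIGN_CHOICES}")
        if self.wall_bc_sign not in _SIGN_CHOICES:
            raise ValueError(f"wall_bc_sign must be one of {_SIGN_CHOICES}")
        if self.energy_diffusivity_weight not in _WEIGHT_CHOICES:
            raise ValueError(
                f"energy_diffusivity_weight must be one of {_WEIGHT_CHOICES}")


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameters of the similarity problem.

    n : power-law index (n < 1 pseudo-plastic, 1 Newtonian, > 1 dilatant)
    M : magnetic parameter (Lorentz-force strength)
    epsilon : stagnation/free-stream straining parameter
    f_w : wall transpiration (suction > 0, injection < 0)
    a : convective (conjugate) heating parameter
    Pr : base-fluid Prandtl number
    ratios : mixture coefficient ratios A1..A4, sigma_bf/sigma_f
    flags : formulation switches
    """

    n: float
    M: float = 0.0
    epsilon: float = 0.0
    f_w: float = 0.0
    a: float = 0.1
    Pr: float = 6.2
    ratios: MixtureRatios = field(default_factory=MixtureRatios.unity)
    flags: FormulationFlags = field(default_factory=FormulationFlags)

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError(f"power-law index n must be > 0, got {self.n}")
        if self.M < 0:
            raise ValueError(f"magnetic parameter M must be >= 0, got {self.M}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.a < 0:
            raise ValueError(f"convective parameter a must be >= 0, got {self.a}")
        if not self.Pr > 0:
            raise ValueError(f"Pr must be > 0, got {self.Pr}")

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)


class State(NamedTuple):
    """First-order state; entries are floats or same-length arrays."""

    f: float | np.ndarray
    fp: float | np.ndarray       # f'
    g: float | np.ndarray        # |f''|^(n-1) f''
    theta: float | np.ndarray
    q: float | np.ndarray        # |f''|^(n-1) theta'  (or theta' unweighted)


def shear_from_g(g, n: float):
    """Recover f'' from the shear variable: f'' = sign(g) |g|^(1/n)."""
    g = np.asarray(g, dtype=float)
    out = np.sign(g) * np.abs(g) ** (1.0 / n)
    return out if out.ndim else float(out)


def regularized_shear_from_g(g, n: float, delta_reg: float):
    """Shear recovery with a finite slope at g = 0 for dilatant fluids.

    For n <= 1 the exact map sign(g)|g|^(1/n) already has a bounded
    derivative at the origin and is used unchanged.  For n > 1 its slope
    diverges where the shear crosses zero (the finite edge of a dilatant
    boundary layer, where the collocation Jacobian would blow up), so the
    smooth blend ``g (g^2 + delta_reg^(2n))^((1-n)/(2n))`` is used instead:
    it matches the exact map to a relative O(delta_reg^(2n)/g^2) away from
    zero and caps the slope at ``delta_reg^(1-n)``.
    """
    g = np.asarray(g, dtype=float)
    if n <= 1.0:
        out = np.sign(g) * np.abs(g) ** (1.0 / n)
    else:
        out = g * (g**2 + delta_reg ** (2.0 * n)) ** ((1.0 - n) / (2.0 * n))
    return out if out.ndim else float(out)


def diffusivity_weight(fpp, n: float, delta_reg: float = 0.0):
    """Factor converting q to theta': max(|f''|, delta_reg)^(1-n)."""
    mag = np.maximum(np.abs(fpp), delta_reg)
    out = mag ** (1.0 - n)
    return out if np.ndim(out) else float(out)


def _thetap(state: State, params: ModelParams, delta_reg: float):
    if params.flags.energy_diffusivity_weight == "unweighted":
        return state.q
    fpp = shear_from_g(state.g, params.n)
    return state.q * diffusivity_weight(fpp, params.n, delta_reg)


def momentum_residual(state: State, params: ModelParams) -> float | np.ndarray:
    """Right-hand side dg/deta of the momentum equation.

    g' = A4 A1 [ -f f''/(n+1) + M^2 (sigma_bf/sigma_f)(f' - 1) + eps^2 ].
    """
    r = params.ratios
    fpp = shear_from_g(state.g, params.n)
    return r.A4 * r.A1 * (
        -state.f * fpp / (params.n + 1.0)
        + params.M**2 * r.sigma_ratio * (state.fp - 1.0)
        + params.epsilon**2
    )


def energy_residual(state: State, params: ModelParams,
                    delta_reg: float = 0.0) -> float | np.ndarray:
    """Right-hand side dq/deta of the energy equation.

    Corrected sign: q' = -(Pr A2/A3) f theta' / (n+1), so wall heating decays
    into the free stream; ``as_printed`` flips the sign (literal rearrangement
    of the printed equation).
    """
    r = params.ratios
    thetap = _thetap(state, params, delta_reg)
    mag = params.Pr * r.A2 / r.A3 * state.f * thetap / (params.n + 1.0)
    return -mag if params.flags.energy_sign == "corrected" else mag


def wall_thermal_residual(theta0, thetap0, params: ModelParams):
    """Residual of the convective wall condition.

    Corrected: theta'(0) + (a/A3)(1 - theta(0))  (from -k_bf dT/dy = h(Tf-Tw));
    as_printed: theta'(0) - A3 a (1 - theta(0)).
    """
    A3 = params.ratios.A3
    if params.flags.wall_bc_sign == "corrected":
        return thetap0 + (params.a / A3) * (1.0 - theta0)
    return thetap0 - A3 * params.a * (1.0 - theta0)


def boundary_residuals(left: State, right: State, params: ModelParams,
                       delta_reg: float = 0.0) -> np.ndarray:
    """Five-component residual vector of the two-point boundary conditions.

    Components: f(0) - f_w, f'(0), f'(eta_inf) - 1, wall thermal condition,
    theta(eta_inf).
    """
    thetap0 = _thetap(left, params, delta_reg)
    return np.array([
        left.f - params.f_w,
        left.fp,
        right.fp - 1.0,
        wall_thermal_residual(left.theta, thetap0, params),
        right.theta,
    ])


def to_first_order(params: ModelParams,
                   delta_reg: float = 1e-8) -> Callable:
    """Assemble the vectorized first-order right-hand side.

    Returns ``rhs(eta, y)`` with ``y = (f, f', g, theta, q)`` stacked along
    axis 0 (shape ``(5,)`` or ``(5, m)``), suitable for both collocation and
    initial-value backends.
    """
    n = params.n
    r = params.ratios
    conv = 1.0 / (n + 1.0)
    A14 = r.A4 * r.A1
    Msig = params.M**2 * r.sigma_ratio
    eps2 = params.epsilon**2
    pr_fac = params.Pr * r.A2 / r.A3 * conv
    energy_sign = -1.0 if params.flags.energy_sign == "corrected" else 1.0
    weighted = params.flags.energy_diffusivity_weight == "f_second_power"

    if n <= 1.0:
        def recover(g):
            return np.sign(g) * np.abs(g) ** (1.0 / n)
    else:
        g_floor2 = delta_reg ** (2.0 * n)
        g_exp = (1.0 - n) / (2.0 * n)

        def recover(g):
            return g * (g**2 + g_floor2) ** g_exp

    def rhs(eta, y):
        f, fp, g, theta, q = np.asarray(y, dtype=float)
        fpp = recover(g)
        if weighted:
            thetap = q * np.maximum(np.abs(fpp), delta_reg) ** (1.0 - n)
        else:
            thetap = q
        dg = A14 * (-conv * f * fpp + Msig * (fp - 1.0) + eps2)
        dq = energy_sign * pr_fac * f * thetap
        return np.stack([fp, fpp, dg, thetap, dq])

    return rhs
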