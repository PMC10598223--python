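"""Effective thermo-physical properties of the particle-laden base fluid.

The boundary-layer model treats the synovial base fluid as a dilute
suspension (volume fraction ``phi``) of a solid phase in a carrier fluid and
closes its effective properties with the classical single-phase mixture
rules used throughout the nanofluid similarity literature:

* Brinkman viscosity  mu_bf/mu_f = (1 - phi)^-2.5,
* Maxwell-Garnett thermal conductivity,
* Maxwell electrical conductivity,
* linear volume-weighted density and heat capacity.

The reduced ODE system consumes only the dimensionless ratios

    A1 = mu_bf/mu_f,  A2 = (rho*Cp)_bf/(rho*Cp)_f,
    A3 = k_bf/k_f,    A4 = rho_bf/rho_f,   sigma_bf/sigma_f,

all of which equal 1 at phi = 0.  For the conductivity closures a literal
``as_printed`` variant is retained behind a flag for auditability; it does
not satisfy the identical-phase transparency limit (value 1 when solid and
fluid properties coincide), so the physically consistent Maxwell forms are
the defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

__all__ = [
    "PhaseProperties",
    "MixtureRatios",
    "effective_viscosity_ratio",
    "effective_conductivity_ratio",
    "effective_density_ratio",
    "effective_heat_capacity_ratio",
    "electrical_conductivity_ratio",
    "build_ratios",
    "water_copper_phases",
]

_CONDUCTIVITY_FORMS = ("maxwell_garnett", "as_printed")
_ELECTRICAL_FORMS = ("maxwell", "as_printed")


@dataclass(frozen=True)
class PhaseProperties:
    """Carrier-fluid (``_f``) and dispersed-phase (``_s``) property set.

    Units: densities kg/m^3, specific heats J/(kg*K), conductivities W/(m*K),
    dynamic viscosity Pa*s, electrical conductivities S/m; ``phi`` is the
    particle volume fraction.
    """

    rho_f: float
    rho_s: float
    cp_f: float
    cp_s: float
    k_f: float
    k_s: float
    mu_f: float
    sigma_f: float
    sigma_s: float
    phi: float

    def __post_init__(self) -> None:
        for name in ("rho_f", "rho_s", "cp_f", "cp_s", "k_f", "k_s",
                     "mu_f", "sigma_f", "sigma_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 <= self.phi < 1:
            raise ValueError(f"phi must lie in [0, 1), got {self.phi}")


@dataclass(frozen=True)
class MixtureRatios:
    """Dimensionless coefficient ratios consumed by the similarity ODEs."""

    A1: float  # mu_bf / mu_f
    A2: float  # (rho*Cp)_bf / (rho*Cp)_f
    A3: float  # k_bf / k_f
    A4: float  # rho_bf / rho_f
    sigma_ratio: float  # sigma_bf / sigma_f
    alpha_bf: float  # effective thermal diffusivity k_bf/(rho*Cp)_bf, m^2/s

    def __post_init__(self) -> None:
        for name in ("A1", "A2", "A3", "A4", "sigma_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @classmethod
    def unity(cls, alpha_bf: float = 1.4711e-07) -> "MixtureRatios":
        """Pure-fluid limit (phi = 0): all ratios 1, water-like diffusivity."""
        return cls(A1=1.0, A2=1.0, A3=1.0, A4=1.0, sigma_ratio=1.0,
                   alpha_bf=alpha_bf)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureRatios":
        return cls(**d)


def effective_viscosity_ratio(phi: float) -> float:
    """Brinkman viscosity ratio mu_bf/mu_f = (1 - phi)^-2.5."""
    if not 0 <= phi < 1:
        raise ValueError(f"phi must lie in [0, 1), got {phi}")
    return (1.0 - phi) ** -2.5


def effective_conductivity_ratio(k_s: float, k_f: float, phi: float,
                                 form: str = "maxwell_garnett") -> float:
    """Thermal conductivity ratio k_bf/k_f for a dilute suspension.

    ``maxwell_garnett`` (default) is the standard closure
    ``[(k_s + 2 k_f) - 2 phi (k_f - k_s)] / [(k_s + 2 k_f) + phi (k_f - k_s)]``,
    transparent for identical phases.  ``as_printed`` keeps the literal
    variant with denominator ``(k_s + 2 k_f) + phi (k_f + k_s)``, which does
    not reduce to 1 for identical phases at phi > 0.
    """
    if k_s <= 0 or k_f <= 0:
        raise ValueError("conductivities must be > 0")
    if not 0 <= phi < 1:
        raise ValueError(f"phi must lie in [0, 1), got {phi}")
    num = (k_s + 2.0 * k_f) - 2.0 * phi * (k_f - k_s)
    if form == "maxwell_garnett":
        den = (k_s + 2.0 * k_f) + phi * (k_f - k_s)
    elif form == "as_printed":
        den = (k_s + 2.0 * k_f) + phi * (k_f + k_s)
    else:
        raise ValueError(f"form must be one of {_CONDUCTIVITY_FORMS}, got {form!r}")
    return num / den


def effective_density_ratio(rho_s: float, rho_f: float, phi: float) -> float:
    """Linear mixture density ratio rho_bf/rho_f = (1 - phi) + phi rho_s/rho_f."""
    if rho_s <= 0 or rho_f <= 0:
        raise ValueError("densities must be > 0")
    if not 0 <= phi < 1:
        raise ValueError(f"phi must lie in [0, 1), got {phi}")
    return (1.0 - phi) + phi * rho_s / rho_f


def effective_heat_capacity_ratio(rho_s: float, cp_s: float, rho_f: float,
                                  cp_f: float, phi: float) -> float:
    """Volumetric heat-capacity ratio (rho*Cp)_bf/(rho*Cp)_f (linear mixture)."""
    if min(rho_s, cp_s, rho_f, cp_f) <= 0:
        raise ValueError("densities and specific heats must be > 0")
    if not 0 <= phi < 1:
        raise ValueError(f"phi must lie in [0, 1), got {phi}")
    return (1.0 - phi) + phi * (rho_s * cp_s) / (rho_f * cp_f)


def electrical_conductivity_ratio(sigma_s: float, sigma_f: float, phi: float,
                                  form: str = "maxwell") -> float:
    """Electrical conductivity ratio sigma_bf/sigma_f.

    ``maxwell`` (default): ``1 + 3 phi (r - 1) / ((r + 2) - phi (r - 1))``
    with ``r = sigma_s/sigma_f``; equals 1 at phi = 0 and at r = 1.
    ``as_printed`` evaluates the literal parenthesisation
    ``1 + (3 phi r - 1) / ((r + 2) - phi r - 1)``.
    """
    if sigma_s <= 0 or sigma_f <= 0:
        raise ValueError("conductivities must be > 0")
    if not 0 <= phi < 1:
        raise ValueError(f"phi must lie in [0, 1), got {phi}")
    r = sigma_s / sigma_f
    if form == "maxwell":
        return 1.0 + 3.0 * phi * (r - 1.0) / ((r + 2.0) - phi * (r - 1.0))
    if form == "as_printed":
        return 1.0 + (3.0 * phi * r - 1.0) / ((r + 2.0) - phi * r - 1.0)
    raise ValueError(f"form must be one of {_ELECTRICAL_FORMS}, got {form!r}")


def build_ratios(props: PhaseProperties,
                 conductivity_form: str = "maxwell_garnett",
                 electrical_form: str = "maxwell") -> MixtureRatios:
    """Assemble all coefficient ratios from a phase property set.

    ``alpha_bf = k_bf / (rho*Cp)_bf`` is the only dimensional output.
    """
    phi = props.phi
    A1 = effective_viscosity_ratio(phi)
    A2 = effective_heat_capacity_ratio(props.rho_s, props.cp_s,
                                       props.rho_f, props.cp_f, phi)
    A3 = effective_conductivity_ratio(props.k_s, props.k_f, phi,
                                      form=conductivity_form)
    A4 = effective_density_ratio(props.rho_s, props.rho_f, phi)
    sigma_ratio = electrical_conductivity_ratio(props.sigma_s, props.sigma_f,
                                                phi, form=electrical_form)
    alpha_bf = (A3 * props.k_f) / (A2 * props.rho_f * props.cp_f)
    return MixtureRatios(A1=A1, A2=A2, A3=A3, A4=A4,
                         sigma_ratio=sigma_ratio, alpha_bf=alpha_bf)


def water_copper_phases(phi: float = 0.01) -> PhaseProperties:
    """Default property set: water carrier with a copper dispersed phase.

    Standard room-temperature table values; the base-fluid Prandtl number is
    an independent model input (default 6.2) and is not recomputed from these.
    """
    return PhaseProperties(
        rho_f=997.1, rho_s=8933.0,
        cp_f=4179.0, cp_s=385.0,
        k_f=0.613, k_s=400.0,
        mu_f=1.003e-3,
        sigma_f=0.05, sigma_s=5.96e7,
        phi=phi,
    )
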