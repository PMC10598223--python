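"""Steady-shear rheology of synovial fluid.

Synovial fluid (SF) owes its shear-thinning behaviour to high-molecular-weight
hyaluronic acid (HA, ~10^7 Da in healthy joints).  Two steady-shear viscosity
models are used here:

* the **Cross model**, ``eta = eta0 / (1 + (c*gdot)**d)``, which interpolates
  between a zero-shear plateau ``eta0`` and a shear-thinning branch with
  relaxation/consistency time ``c`` (s) and rate index ``d``;
* its high-shear **power-law** limit, ``eta = eta0 / (c*gdot)**d``, which for
  ``c*gdot >> 1`` coincides with the Cross model and maps onto the
  Ostwald-de Waele form ``sigma = K * gdot**n`` with ``K = eta0 / c**d`` and
  ``n = 1 - d``.

Clinical rheometry classifies SF samples from the power-law pair ``(K, n)``:
"mechanical" (normal/non-inflammatory) fluids are viscous and strongly
shear-thinning (K > 0.03, n < 0.85), "inflammatory" fluids are thin and nearly
Newtonian (K < 0.01, n > 0.85), everything else — including values sitting
exactly on a threshold — is "intermediate".

Intrinsic viscosity of HA solutions follows the Mark-Houwink relation
``eta = 0.036 * Mv**0.78`` with ``Mv`` the viscosity-average molecular weight
in Dalton.  Units throughout: viscosities in Pa*s, ``c`` in s, shear rates in
1/s; the Mark-Houwink number is treated as dimensionless.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CrossParams",
    "PowerLawParams",
    "FluidClass",
    "cross_viscosity",
    "power_law_viscosity",
    "power_law_from_cross",
    "cross_from_power_law",
    "mark_houwink_viscosity",
    "classify_fluid",
    "reference_ranges",
    "joint_fluid_composition",
]

#: Mark-Houwink prefactor and exponent for hyaluronic acid.
MARK_HOUWINK_K = 0.036
MARK_HOUWINK_A = 0.78

#: Classification thresholds on the power-law pair (K, n).
K_MECHANICAL = 0.03
K_INFLAMMATORY = 0.01
N_THRESHOLD = 0.85


@dataclass(frozen=True)
class CrossParams:
    """Cross-model parameter triple (eta0 [Pa*s], c [s], d [-])."""

    eta0: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.eta0 > 0:
            raise ValueError(f"eta0 must be > 0, got {self.eta0}")
        if not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if not 0 <= self.d < 1:
            raise ValueError(f"d must lie in [0, 1), got {self.d}")


@dataclass(frozen=True)
class PowerLawParams:
    """Ostwald-de Waele pair (K [Pa*s^n], n [-])."""

    K: float
    n: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if not self.n > 0:
            raise ValueError(f"n must be > 0, got {self.n}")

    @property
    def dilatant(self) -> bool:
        """True for shear-thickening behaviour (n > 1)."""
        return self.n > 1


class FluidClass(str, enum.Enum):
    """Clinical SF class inferred from the power-law pair."""

    MECHANICAL = "mechanical"
    INFLAMMATORY = "inflammatory"
    INTERMEDIATE = "intermediate"


def cross_viscosity(p: CrossParams, shear_rate):
    """Cross-model apparent viscosity eta0 / (1 + (c*gdot)**d).

    Parameters
    ----------
    p : CrossParams
    shear_rate : float or array_like
        Shear rate gdot >= 0 in 1/s.

    Returns
    -------
    float or ndarray
        Apparent viscosity in Pa*s; equals ``eta0`` at zero shear (d > 0)
        and decreases monotonically with shear rate.
    """
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0):
        raise ValueError("shear_rate must be >= 0")
    eta = p.eta0 / (1.0 + (p.c * gdot) ** p.d)
    return eta if eta.ndim else float(eta)


def power_law_viscosity(p: CrossParams, shear_rate):
    """High-shear power-law viscosity eta0 / (c*gdot)**d.

    Valid for ``c*gdot >> 1``; diverges as gdot -> 0 when d > 0, so zero
    shear rate is rejected for d > 0.  The branch overshoots the full Cross
    model by exactly ``1 / (1 + (c*gdot)**d)`` of its own value.
    """
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0):
        raise ValueError("shear_rate must be >= 0")
    if p.d > 0 and np.any(gdot == 0):
        raise ValueError("power-law viscosity diverges at zero shear rate for d > 0")
    eta = p.eta0 / (p.c * gdot) ** p.d
    return eta if eta.ndim else float(eta)


def power_law_from_cross(p: CrossParams) -> PowerLawParams:
    """Map Cross parameters to the equivalent power-law pair.

    ``K = eta0 / c**d`` and ``n = 1 - d``; exact on the shear-thinning
    branch, with ``d = 0`` recovering the Newtonian limit ``(K, n) = (eta0, 1)``.
    """
    return PowerLawParams(K=p.eta0 / p.c**p.d, n=1.0 - p.d)


def cross_from_power_law(p: PowerLawParams, c: float) -> CrossParams:
    """Invert :func:`power_law_from_cross` given the consistency time ``c``."""
    if not 0 < p.n <= 1:
        raise ValueError("Cross equivalence requires 0 < n <= 1")
    d = 1.0 - p.n
    return CrossParams(eta0=p.K * c**d, c=c, d=d)


def mark_houwink_viscosity(Mv):
    """Intrinsic viscosity of HA from its molecular weight (Dalton)."""
    Mv = np.asarray(Mv, dtype=float)
    if np.any(Mv <= 0):
        raise ValueError("molecular weight must be > 0")
    eta = MARK_HOUWINK_K * Mv**MARK_HOUWINK_A
    return eta if eta.ndim else float(eta)


def classify_fluid(p: PowerLawParams | CrossParams) -> FluidClass:
    """Classify an SF sample from its power-law pair.

    Accepts either representation; Cross parameters are converted first.
    Strict inequalities are used, so values sitting exactly on a threshold
    fall in the intermediate ("middle ground") class.
    """
    if isinstance(p, CrossParams):
        p = power_law_from_cross(p)
    if p.K > K_MECHANICAL and p.n < N_THRESHOLD:
        return FluidClass.MECHANICAL
    if p.K < K_INFLAMMATORY and p.n > N_THRESHOLD:
        return FluidClass.INFLAMMATORY
    return FluidClass.INTERMEDIATE


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("synovia.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def reference_ranges() -> pd.DataFrame:
    """Literature ranges of Cross parameters by patient population.

    Columns: population, n_samples, eta0_lo/hi (Pa*s), c_lo/hi (s), d,
    ha_mg_ml (HA concentration), reliable (False where the source table is
    garbled — those rows should not be used quantitatively), note.
    """
    df = _load_csv("reference_ranges.csv")
    df["reliable"] = df["reliable"].astype(bool)
    return df


def joint_fluid_composition() -> pd.DataFrame:
    """Reference concentrations of protein, HA and phospholipids in joint fluid."""
    return _load_csv("joint_fluid_composition.csv")
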