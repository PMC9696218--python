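"""Temperature dependence of persistence length via a linear buckling-length law.

The procedure has three steps.  First, an empirical temperature law for the
persistence length of short cyclized DNA (Geggier et al.'s fit) is inverted
through the buckling map — cyclized fragments are taken as clamp-clamp,
mu = 0.5 — giving the critical buckling length at each temperature.  Second,
an ordinary least-squares line lcb(T) = a + g*T is fitted to those points.
Third, the gradient g is transferred to other constraint classes by anchoring
the line at each class's mean buckling length at 298 K.  Predicted lp(T)
curves follow by pushing the linear lcb(T) back through the buckling map with
the temperature-dependent permittivity and force scale.

The reference gradient obtained from the cyclization inversion is
-0.0359 nm/K; the transfer arithmetic anchored at the class means 5.95 nm
(suspended) and 8.43 nm (fix-bead) gives intercepts 16.65 nm and 19.13 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .buckling import EndConstraint
from .errors import DomainError
from .media_forces import CONSTANTS, DnaGeometry, Medium
from .persistence_map import buckling_from_persistence, lp_from_lcb
from .media_forces import reduced_electrostatic_force

__all__ = [
    "LinearLcbModel",
    "REFERENCE_LCB_GRADIENT",
    "DEFAULT_T_GRID",
    "geggier_lp",
    "fit_lcb_vs_T",
    "transfer_gradient",
    "lp_vs_temperature",
]

#: Reference gradient of critical buckling length with temperature, m/K,
#: from the linear fit to the inverted cyclization law.
REFERENCE_LCB_GRADIENT = -0.0359e-9

#: Default temperature window (no denaturation), 1 K steps.
DEFAULT_T_GRID = np.arange(278.0, 313.0 + 0.5, 1.0)

#: Validity window of the cyclization empirical law, K.
_T_WINDOW = (278.0, 313.0)


@dataclass(frozen=True)
class LinearLcbModel:
    """lcb(T) = intercept_a + gradient_g * T, lengths in meters, T in kelvin."""

    intercept_a: float
    gradient_g: float

    def lcb(self, T: float) -> float:
        val = self.intercept_a + self.gradient_g * T
        if val <= 0:
            raise DomainError(
                f"linear model gives non-positive lcb = {val} m at T = {T} K"
            )
        return val


def geggier_lp(T: float) -> float:
    """Empirical cyclization persistence length, in meters.

    lp(T) = (3.19 - 0.00414 T) x 10^-19 / (kB T), read in nanometers (the
    numerator is an energy scale in units of 10^-19 J; dividing by kB*T in
    joules leaves the dimensionless nm count — ~47.6 nm at 298 K).  Strictly
    decreasing over the 278–313 K window.
    """
    if T <= 0:
        raise DomainError(f"temperature must be positive, got {T} K")
    lp_nm = (3.19 - 0.00414 * T) * 1e-19 / (CONSTANTS.kB * T)
    if lp_nm <= 0:
        raise DomainError(f"empirical law gives non-positive lp at T = {T} K")
    return lp_nm * 1e-9


def fit_lcb_vs_T(
    lp_of_T: Callable[[float], float],
    mu: float,
    medium_of_T: Callable[[float], Medium],
    geom: DnaGeometry = DnaGeometry(),
    T_grid: Sequence[float] = DEFAULT_T_GRID,
) -> LinearLcbModel:
    """Invert lp(T) to lcb(T) pointwise and fit an ordinary least-squares line.

    ``medium_of_T`` must supply the medium at each temperature (so the
    permittivity and force scale track T).  A non-physical inversion at any
    grid point raises, naming the temperature.
    """
    T = np.asarray(T_grid, dtype=float)
    if T.size < 2:
        raise DomainError(f"need >= 2 temperatures, got {T.size}")
    constraint = EndConstraint(mu)
    lcbs = []
    for Ti in T:
        try:
            lcbs.append(
                buckling_from_persistence(lp_of_T(Ti), constraint, medium_of_T(Ti), geom)
            )
        except Exception as exc:
            raise DomainError(f"inversion failed at T = {Ti} K: {exc}") from exc
    g, a = np.polyfit(T, np.array(lcbs), 1)
    return LinearLcbModel(intercept_a=float(a), gradient_g=float(g))


def transfer_gradient(lcb_at_298: float, gradient_g: float) -> LinearLcbModel:
    """Anchor a linear lcb(T) law at (298 K, lcb_at_298) with the given gradient.

    intercept = lcb_at_298 - g * 298, so the returned model passes through
    the anchor point exactly.
    """
    if lcb_at_298 <= 0:
        raise DomainError(f"lcb at 298 K must be positive, got {lcb_at_298}")
    return LinearLcbModel(
        intercept_a=lcb_at_298 - gradient_g * 298.0, gradient_g=gradient_g
    )


def lp_vs_temperature(
    model: LinearLcbModel,
    mu: float,
    medium_template: Medium,
    geom: DnaGeometry = DnaGeometry(),
    T_grid: Sequence[float] = DEFAULT_T_GRID,
) -> list[tuple[float, float]]:
    """Predicted (T, lp) series for a constraint class.

    The template fixes c and Z; the permittivity (and hence the force scale)
    is recomputed at each temperature from the linear dielectric law.
    """
    if mu <= 0:
        raise DomainError(f"mu must be positive, got {mu}")
    out = []
    for Ti in np.asarray(T_grid, dtype=float):
        med = Medium(c=medium_template.c, Z=medium_template.Z, T=float(Ti))
        f = reduced_electrostatic_force(med, geom)
        lp = float(lp_from_lcb(mu, model.lcb(float(Ti)), f, geom.R))
        out.append((float(Ti), lp))
    return out
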