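"""Ionic/thermal environment and the two axial force laws acting on a DNA fragment.

A bent double-stranded DNA fragment isolated from a longer chain is loaded
axially by two statistical forces: the compressive support reaction generated
by the screened electrostatic self-repulsion of the charged backbone
(Manning's counterion-condensation form), and the reaction generated by
thermal fluctuations of the fragment.  This module provides the physical
constants, the temperature-dependent dielectric model for water, the Bjerrum
and Debye screening lengths, and both force laws.

All quantities are SI internally (meters, newtons, kelvin); concentrations
enter in mol/L and are converted to number densities inside ``debye_length``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import DomainError

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "Medium",
    "DnaGeometry",
    "AxialForces",
    "relative_permittivity",
    "bjerrum_length",
    "debye_length",
    "condensation_parameter",
    "electrostatic_force",
    "reduced_electrostatic_force",
    "thermal_force",
    "DIELECTRIC_T_WINDOW",
]

#: Validity window of the linear dielectric law for water, in kelvin.
DIELECTRIC_T_WINDOW = (278.0, 313.0)


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants, at the precision used throughout the model.

    kB : Boltzmann constant, J/K
    q : elementary charge, C
    eps0 : vacuum permittivity, F/m
    NA : Avogadro constant, 1/mol
    """

    kB: float = 1.38e-23
    q: float = 1.6e-19
    eps0: float = 8.85e-12
    NA: float = 6.022e23

    def __post_init__(self) -> None:
        for name in ("kB", "q", "eps0", "NA"):
            if getattr(self, name) <= 0:
                raise DomainError(f"constant {name} must be strictly positive")


#: Shared read-only constant set.
CONSTANTS = PhysicalConstants()


def relative_permittivity(T: float) -> float:
    """Relative permittivity of water, linear in temperature.

    Returns ``87.74 - 0.4 (T - 293)`` with *T* in kelvin.  The linear law is
    calibrated between 278 K and 313 K; temperatures outside that window give
    a warning but are still evaluated (extrapolation, not an error).
    """
    if T <= 0:
        raise DomainError(f"temperature must be positive, got {T} K")
    lo, hi = DIELECTRIC_T_WINDOW
    if not lo <= T <= hi:
        warnings.warn(
            f"T = {T} K is outside the dielectric law's validity window "
            f"[{lo}, {hi}] K; the linear formula is extrapolated",
            stacklevel=2,
        )
    return 87.74 - 0.4 * (T - 293.0)


@dataclass(frozen=True)
class Medium:
    """A single-salt ionic environment.

    c : counterion concentration, mol/L (strictly positive)
    Z : unsigned counterion valence (1 for Na+, 2 for Mg2+, ...)
    T : temperature, K
    eps_r : relative permittivity; derived from ``relative_permittivity(T)``
        unless explicitly overridden (useful for sensitivity studies).
    """

    c: float
    Z: int = 1
    T: float = 298.0
    eps_r: float | None = None

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise DomainError(f"concentration must be positive, got {self.c} mol/L")
        if int(self.Z) != self.Z or self.Z < 1:
            raise DomainError(f"valence must be an integer >= 1, got {self.Z}")
        if self.T <= 0:
            raise DomainError(f"temperature must be positive, got {self.T} K")
        if self.eps_r is not None and self.eps_r <= 0:
            raise DomainError(f"eps_r must be positive, got {self.eps_r}")

    @property
    def permittivity(self) -> float:
        """Resolved relative permittivity (override or linear law)."""
        if self.eps_r is not None:
            return self.eps_r
        return relative_permittivity(self.T)


@dataclass(frozen=True)
class DnaGeometry:
    """Cross-section and charge geometry of B-DNA.

    R : cross-section radius, m (default 1 nm)
    b : axial spacing of backbone charges, m (default 0.17 nm)
    """

    R: float = 1e-9
    b: float = 0.17e-9

    def __post_init__(self) -> None:
        if self.R <= 0 or self.b <= 0:
            raise DomainError(f"R and b must be positive, got R={self.R}, b={self.b}")

    @property
    def area(self) -> float:
        """Cross-section area A = pi R^2, m^2."""
        return math.pi * self.R**2

    @property
    def inertia(self) -> float:
        """Second moment of area I = pi R^4 / 4, m^4."""
        return math.pi * self.R**4 / 4.0


@dataclass(frozen=True)
class AxialForces:
    """The two axial support-reaction forces on a fragment, in newtons.

    F_tf is non-negative by construction; F_ele changes sign at very high
    salt, where screening kills the repulsive bracket.
    """

    F_ele: float
    F_tf: float

    def __post_init__(self) -> None:
        if self.F_tf < 0:
            raise DomainError(f"thermal force cannot be negative, got {self.F_tf}")

    @property
    def total(self) -> float:
        return self.F_ele + self.F_tf


def bjerrum_length(
    T: float, eps_r: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Bjerrum length lB = q^2 / (4 pi eps0 eps_r kB T), in meters.

    The separation at which two elementary charges interact with thermal
    energy kB*T; ~0.65 nm in water at 298 K.
    """
    if T <= 0 or eps_r <= 0:
        raise DomainError(f"need T > 0 and eps_r > 0, got T={T}, eps_r={eps_r}")
    k = constants
    return k.q**2 / (4.0 * math.pi * k.eps0 * eps_r * k.kB * T)


def debye_length(medium: Medium, constants: PhysicalConstants = CONSTANTS) -> float:
    """Debye screening length lambda_D = sqrt(eps0 eps_r kB T / (c NA q^2 Z^2)), m.

    The concentration is the counterion concentration in mol/L, converted to
    mol/m^3 with the factor 1000 before multiplying by NA.
    """
    k = constants
    c_per_m3 = medium.c * 1000.0 * k.NA  # particles per m^3
    num = k.eps0 * medium.permittivity * k.kB * medium.T
    den = c_per_m3 * k.q**2 * medium.Z**2
    return math.sqrt(num / den)


def condensation_parameter(medium: Medium, geom: DnaGeometry) -> float:
    """Manning's dimensionless charge density xi = lB / b (~4.2 for B-DNA)."""
    lB = bjerrum_length(medium.T, medium.permittivity)
    return lB / geom.b


def electrostatic_force(
    medium: Medium, geom: DnaGeometry, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Axial support reaction from screened electrostatic repulsion, in newtons.

    Manning's condensation form::

        F_ele = kB T / (Z^2 lB) * [ (2 Z xi - 1) kb e^{-kb} / (1 - e^{-kb})
                                    - 1 - ln(1 - e^{-kb}) ]

    with ``kb = b / lambda_D`` and ``xi = lB / b``.  The bracket diverges
    logarithmically as c -> 0 and tends to -1 as c -> infinity, so the force
    is compressive (positive) throughout the experimentally relevant salt
    range and approaches ``-kB T / (Z^2 lB)`` at extreme ionic strength.
    """
    k = constants
    lB = bjerrum_length(medium.T, medium.permittivity, k)
    lam = debye_length(medium, k)
    kb = geom.b / lam
    if kb <= 0:
        raise DomainError("kappa*b must be positive (c = 0 is unsupported)")
    xi = lB / geom.b
    emkb = math.exp(-kb)
    one_minus = -math.expm1(-kb)  # 1 - e^{-kb}, accurate for small kb
    bracket = (2.0 * medium.Z * xi - 1.0) * kb * emkb / one_minus - 1.0 - math.log(one_minus)
    return k.kB * medium.T / (medium.Z**2 * lB) * bracket


def reduced_electrostatic_force(
    medium: Medium, geom: DnaGeometry, constants: PhysicalConstants = CONSTANTS
) -> float:
    """F_ele / (kB T): the inverse-length force scale entering the buckling map, 1/m."""
    return electrostatic_force(medium, geom, constants) / (constants.kB * medium.T)


def thermal_force(
    lp: float,
    lcb: float,
    geom: DnaGeometry,
    T: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Axial support reaction from thermal fluctuations, in newtons.

    F_tf = sqrt(EA kB T / lcb), with the stretch modulus eliminated through
    the wormlike-chain identity EI = kB T lp and I = A R^2 / 4, i.e.
    EA = 4 kB T lp / R^2, giving::

        F_tf = (2 kB T / R) sqrt(lp / lcb)

    It vanishes with lp (no bending stiffness, no fluctuation force) and
    scales as sqrt(lp/lcb) at fixed geometry and temperature.
    """
    if lp < 0 or lcb <= 0:
        raise DomainError(f"need lp >= 0 and lcb > 0, got lp={lp}, lcb={lcb}")
    if T <= 0:
        raise DomainError(f"temperature must be positive, got {T} K")
    return 2.0 * constants.kB * T / geom.R * math.sqrt(lp / lcb)
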