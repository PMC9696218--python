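"""The bidirectional map between persistence length and critical buckling length.

Balancing the electrostatic and thermal axial reactions against the Euler
critical load of the end-constrained fragment, with the wormlike-chain
identity EI = kB T lp, yields a characteristic polynomial that is quartic in
the critical buckling length lcb and quadratic in the persistence length lp
(f = F_ele / kB T, an inverse length):

    f^2 lcb^4 - (4 lp / R^2) lcb^3 - (2 pi^2 f lp / mu^2) lcb^2
        + (pi^4 / mu^4) lp^2 = 0

Solving for lp on the physical branch gives the explicit three-term form

    lp = (1 / pi^4 R^2) [ 2 mu^4 lcb^3
                          + 2 mu^3 lcb^{5/2} sqrt(mu^2 lcb + pi^2 R^2 f)
                          + pi^2 mu^2 R^2 lcb^2 f ]

whose terms are, in order: the term only depending on the constraint (TODC),
the term weakly depending on the environment through the square root (TWDE),
and the term strongly (linearly) depending on the environment (TSDE).

Degenerate limits: with F_ele = 0 and mu = 1/2 the map collapses to the
null-isomer law lp* = lcb*^3 / (4 pi^4 R^2); dropping the thermal reaction
instead gives lp = mu^2 lcb^2 f / pi^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .buckling import EndConstraint
from .errors import DomainError, SolveError
from .media_forces import (
    CONSTANTS,
    DnaGeometry,
    Medium,
    reduced_electrostatic_force,
)

__all__ = [
    "BucklingModel",
    "PersistenceDecomposition",
    "persistence_from_buckling",
    "buckling_from_persistence",
    "decompose",
    "predict_curve",
    "characteristic_residual",
    "lp_from_lcb",
    "lcb_from_lp",
]

_PI2 = math.pi**2
_PI4 = math.pi**4


@dataclass(frozen=True)
class BucklingModel:
    """An end-constraint/buckling-length pair with its cross-section geometry."""

    constraint: EndConstraint
    lcb: float
    geom: DnaGeometry = DnaGeometry()

    def __post_init__(self) -> None:
        if self.lcb <= 0:
            raise DomainError(f"critical buckling length must be positive, got {self.lcb}")

    @property
    def mu(self) -> float:
        return self.constraint.mu


@dataclass(frozen=True)
class PersistenceDecomposition:
    """Additive split of the predicted persistence length, in meters.

    todc: constraint-only term; independent of the ionic condition.
    twde: square-root coupling term; varies mildly with the environment and
        collapses to the constraint-only value when F_ele = 0.
    tsde: linear coupling term, proportional to F_ele / kB T; it carries most
        of the salt and temperature dependence and vanishes when F_ele = 0.
    """

    todc: float
    twde: float
    tsde: float

    @property
    def total(self) -> float:
        return self.todc + self.twde + self.tsde


# ---------------------------------------------------------------------------
# Functional core (mu, lcb, f, R) -- vectorized over numpy arrays.
# ---------------------------------------------------------------------------

def lp_from_lcb(mu, lcb, f, R):
    """Persistence length from (mu, lcb, f=F_ele/kBT, R); broadcasts.

    Implemented as the physical (larger) root of the characteristic
    polynomial treated as a quadratic in lp, via the numerically stable
    quadratic formula; algebraically identical to the explicit three-term
    expression (see :func:`decompose_terms`).
    """
    mu = np.asarray(mu, dtype=float)
    lcb = np.asarray(lcb, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(mu <= 0) or np.any(lcb <= 0):
        raise DomainError("mu and lcb must be strictly positive")
    a = _PI4 / mu**4
    b = 4.0 * lcb**3 / R**2 + 2.0 * _PI2 * f * lcb**2 / mu**2
    c = f**2 * lcb**4
    disc = b**2 - 4.0 * a * c  # = (16 lcb^5 / R^2)(lcb / R^2 + pi^2 f / mu^2)
    if np.any(disc < 0):
        raise SolveError(
            "no positive real persistence length: discriminant negative "
            f"(mu={mu}, lcb={lcb}, f={f}); the electrostatic force is too "
            "strongly negative for a buckled state"
        )
    lp = (b + np.sqrt(disc)) / (2.0 * a)
    return lp if lp.ndim else float(lp)


def decompose_terms(mu, lcb, f, R):
    """The three additive terms (todc, twde, tsde) of the explicit map."""
    mu = np.asarray(mu, dtype=float)
    lcb = np.asarray(lcb, dtype=float)
    f = np.asarray(f, dtype=float)
    inner = mu**2 * lcb + _PI2 * R**2 * f
    if np.any(inner < 0):
        raise SolveError(
            f"no positive real persistence length at mu={mu}, lcb={lcb}, f={f}"
        )
    todc = 2.0 * mu**4 * lcb**3 / (_PI4 * R**2)
    twde = 2.0 * mu**3 * lcb**2.5 * np.sqrt(inner) / (_PI4 * R**2)
    tsde = mu**2 * lcb**2 * f / _PI2
    return todc, twde, tsde


def lcb_from_lp(mu, lp, f, R, rtol: float = 1e-6):
    """Critical buckling length from (mu, lp, f, R): the branch-consistent
    positive real root of the quartic; scalars only.

    The quartic is solved in nanometer scale through the companion matrix;
    among its positive real roots, the physical branch is the one that maps
    back to lp through :func:`lp_from_lcb` within ``rtol`` (ties broken by
    smallest round-trip error).
    """
    if lp <= 0 or mu <= 0:
        raise DomainError(f"need lp > 0 and mu > 0, got lp={lp}, mu={mu}")
    s = 1e-9  # solve for u = lcb / s to condition the companion matrix
    coeffs = [
        f**2 * s**4,
        -4.0 * lp * s**3 / R**2,
        -2.0 * _PI2 * f * lp * s**2 / mu**2,
        0.0,
        _PI4 * lp**2 / mu**4,
    ]
    if coeffs[0] == 0.0:
        # F_ele = 0: the quartic degenerates to a cubic with closed form.
        return (_PI4 * R**2 * lp / (4.0 * mu**4)) ** (1.0 / 3.0)
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9 * np.abs(roots.real).max()].real
    candidates = sorted(u * s for u in real if u > 0)
    best, best_err = None, math.inf
    for r in candidates:
        err = abs(lp_from_lcb(mu, r, f, R) - lp) / lp
        if err < best_err:
            best, best_err = r, err
    if best is None or best_err > rtol:
        raise SolveError(
            f"no branch-consistent quartic root for lp={lp}, mu={mu}, f={f}; "
            f"real roots (m): {sorted(u * s for u in real)}"
        )
    return best


def characteristic_residual(mu, lcb, lp, f, R):
    """Value of the quartic/quadratic characteristic polynomial, for checks.

    Evaluated in nanometer scale so the residual is comparable to the
    magnitude of its own leading terms.
    """
    s = 1e-9
    x, p, g = lcb / s, lp / s, f * s
    r_nm = R / s
    return (
        g**2 * x**4
        - 4.0 * p * x**3 / r_nm**2
        - 2.0 * _PI2 * g * p * x**2 / mu**2
        + _PI4 * p**2 / mu**4
    )


# ---------------------------------------------------------------------------
# Object-level API.
# ---------------------------------------------------------------------------

def persistence_from_buckling(model: BucklingModel, medium: Medium) -> float:
    """Predicted persistence length (m) of a fragment in the given medium."""
    f = reduced_electrostatic_force(medium, model.geom)
    return float(lp_from_lcb(model.mu, model.lcb, f, model.geom.R))


def buckling_from_persistence(
    lp: float,
    constraint: EndConstraint,
    medium: Medium,
    geom: DnaGeometry = DnaGeometry(),
) -> float:
    """Critical buckling length (m) consistent with an observed persistence length."""
    f = reduced_electrostatic_force(medium, geom)
    return lcb_from_lp(constraint.mu, lp, f, geom.R)


def decompose(model: BucklingModel, medium: Medium) -> PersistenceDecomposition:
    """Split the predicted persistence length into TODC + TWDE + TSDE."""
    f = reduced_electrostatic_force(medium, model.geom)
    todc, twde, tsde = decompose_terms(model.mu, model.lcb, f, model.geom.R)
    return PersistenceDecomposition(float(todc), float(twde), float(tsde))


def predict_curve(
    model: BucklingModel,
    conditions: Sequence[Medium],
    sigma_mu: float = 0.0,
) -> list[tuple[float, float, float]]:
    """Predicted lp with an uncertainty band from the spread of mu.

    The central value is evaluated at mu, the band endpoints at mu +/- sigma_mu
    with lcb held fixed (the spread of lcb is deliberately not propagated, to
    avoid double-counting the statistical scatter of the fitted parameters).
    Returns one ``(lp, lp_low, lp_high)`` triple per condition, low <= high.
    """
    if sigma_mu < 0:
        raise DomainError(f"sigma_mu must be non-negative, got {sigma_mu}")
    if model.mu - sigma_mu <= 0:
        raise DomainError(
            f"mu - sigma_mu = {model.mu - sigma_mu} is not positive; band undefined"
        )
    out = []
    R = model.geom.R
    for med in conditions:
        f = reduced_electrostatic_force(med, model.geom)
        central = float(lp_from_lcb(model.mu, model.lcb, f, R))
        lo = float(lp_from_lcb(model.mu - sigma_mu, model.lcb, f, R))
        hi = float(lp_from_lcb(model.mu + sigma_mu, model.lcb, f, R))
        lo, hi = min(lo, hi), max(lo, hi)
        out.append((central, lo, hi))
    return out
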