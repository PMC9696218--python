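"""Euler buckling of an end-constrained column: effective length factors.

The isolated DNA fragment is treated as an axially loaded elastic column
whose ends are restrained by rotational springs, with a lateral spring
resisting relative sway of the ends (the constraint exerted by the adjacent
fragments of the chain).  The end condition enters the persistence-length
map only through the effective length factor

    mu = pi * sqrt(EI / P1) / L,

the ratio converting the constrained column's critical load P1 to the
equivalent hinge-hinge case.  Classical anchors: hinge-hinge 1.0,
clamp-clamp 0.5, clamp-hinge ~0.699, clamp-free (cantilever) 2.0.

The spring model is a reconstruction from standard column theory: deflection
y(x) = A sin kx + B cos kx + C x + D with k^2 = P/EI, one end held laterally
with a rotational spring, the other end carrying a rotational spring and a
lateral spring; the characteristic function is the 4x4 boundary-condition
determinant, and the lowest buckling load is its smallest positive root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, SolveError

__all__ = [
    "EndConstraint",
    "BucklingState",
    "RIGID",
    "critical_length_from_load",
    "critical_load",
    "mu_from_springs",
    "MU_HINGE_HINGE",
    "MU_CLAMP_CLAMP",
    "MU_CLAMP_HINGE",
    "MU_CLAMP_FREE",
]

#: Dimensionless stiffness (k_rot L / EI or k_lat L^3 / EI) above which an end
#: is treated as rigid and the exact clamped/held boundary row is used instead
#: of the spring row.  Documented sentinel; ``math.inf`` is also accepted.
RIGID = 1e8

# Classical effective length factors, for reference and testing.
MU_HINGE_HINGE = 1.0
MU_CLAMP_CLAMP = 0.5
MU_CLAMP_HINGE = 0.6991573072677265  # pi / alpha with tan(alpha) = alpha
MU_CLAMP_FREE = 2.0


@dataclass(frozen=True)
class EndConstraint:
    """End-constraint condition summarized by the effective length factor mu."""

    mu: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise DomainError(f"effective length factor must be positive, got {self.mu}")

    @classmethod
    def from_springs(
        cls,
        k_rot_left: float,
        k_rot_right: float,
        k_lat: float,
        EI: float = 1.0,
        L: float = 1.0,
    ) -> "EndConstraint":
        return cls(mu_from_springs(k_rot_left, k_rot_right, k_lat, EI, L))


@dataclass(frozen=True)
class BucklingState:
    """A fragment length paired with its end-constraint condition."""

    lcb: float
    constraint: EndConstraint

    def __post_init__(self) -> None:
        if self.lcb <= 0:
            raise DomainError(f"critical buckling length must be positive, got {self.lcb}")


def critical_length_from_load(P: float, EI: float, mu: float) -> float:
    """Critical buckling length lcb = (pi / mu) sqrt(EI / P).

    Equivalently P = pi^2 EI / (mu lcb)^2.  Compression only: P <= 0 raises.
    """
    if P <= 0:
        raise DomainError(f"no buckling under tension or zero load, got P={P}")
    if EI <= 0 or mu <= 0:
        raise DomainError(f"need EI > 0 and mu > 0, got EI={EI}, mu={mu}")
    return math.pi / mu * math.sqrt(EI / P)


def critical_load(lcb: float, EI: float, mu: float) -> float:
    """Inverse of :func:`critical_length_from_load`: P = pi^2 EI / (mu lcb)^2."""
    if lcb <= 0 or EI <= 0 or mu <= 0:
        raise DomainError(f"need positive lcb, EI, mu; got {lcb}, {EI}, {mu}")
    return math.pi**2 * EI / (mu * lcb) ** 2


def _is_rigid(stiffness_dimless: float) -> bool:
    return math.isinf(stiffness_dimless) or stiffness_dimless >= RIGID


def _characteristic_det(alpha: float, r0: float, rL: float, t: float) -> float:
    """Boundary-condition determinant at alpha = kL.

    r0, rL: dimensionless rotational stiffnesses k_rot L / EI at x=0, x=L.
    t: dimensionless lateral stiffness k_lat L^3 / EI at x=L (x=0 is held).
    Rigid ends are substituted with exact clamped/held rows.

    Rows act on coefficients (A, B, C, D) of y = A sin kx + B cos kx + Cx + D,
    written in the scaled variable s = x/L so that only alpha appears:

      1. y(0) = 0
      2. moment balance at x=0:  y''(0) = r0 y'(0)   (or y'(0) = 0 if rigid)
      3. moment balance at x=L:  y''(L) = -rL y'(L)  (or y'(L) = 0 if rigid)
      4. shear balance at x=L:  -y''' - alpha^2 y' + t y = 0, which reduces to
         -alpha^2 C + t y(L) = 0  (or y(L) = 0 if rigid)
    """
    sa, ca = math.sin(alpha), math.cos(alpha)
    rows = []
    # Row 1: y(0) = 0 -> B + D = 0.
    rows.append([0.0, 1.0, 0.0, 1.0])
    # Row 2: end x=0 rotational spring.
    if _is_rigid(r0):
        # y'(0) = 0 -> alpha A + C = 0 (derivatives w.r.t. s = x/L).
        rows.append([alpha, 0.0, 1.0, 0.0])
    else:
        # y''(0) - r0 y'(0) = 0 -> -alpha^2 B - r0 (alpha A + C) = 0.
        rows.append([-r0 * alpha, -(alpha**2), -r0, 0.0])
    # Row 3: end x=L rotational spring (mirror sign).
    if _is_rigid(rL):
        rows.append([alpha * ca, -alpha * sa, 1.0, 0.0])
    else:
        # y''(L) + rL y'(L) = 0.
        rows.append(
            [
                -(alpha**2) * sa + rL * alpha * ca,
                -(alpha**2) * ca - rL * alpha * sa,
                rL,
                0.0,
            ]
        )
    # Row 4: lateral spring at x=L.
    if _is_rigid(t):
        rows.append([sa, ca, 1.0, 1.0])
    else:
        # -alpha^2 C + t (A sin a + B cos a + C + D) = 0.
        rows.append([t * sa, t * ca, t - alpha**2, t])
    m = np.array(rows, dtype=float)
    # Normalize rows so the determinant stays O(1) across the alpha scan.
    scale = np.max(np.abs(m), axis=1)
    scale[scale == 0.0] = 1.0
    return float(np.linalg.det(m / scale[:, None]))


def mu_from_springs(
    k_rot_left: float,
    k_rot_right: float,
    k_lat: float,
    EI: float,
    L: float,
    *,
    alpha_max: float = 2.0 * math.pi + 0.5,
    n_scan: int = 4000,
    xtol: float = 1e-12,
) -> float:
    """Effective length factor of a column with elastic end restraints.

    Parameters are the physical spring stiffnesses: rotational springs at the
    two ends (N m/rad, 0 = free to rotate) and a lateral spring resisting end
    sway (N/m, 0 = free to sway); ``math.inf`` or any dimensionless stiffness
    above :data:`RIGID` means rigid.  The smallest positive root alpha1 of the
    characteristic determinant gives P1 = alpha1^2 EI / L^2 and
    mu = pi / alpha1.

    mu is continuous and non-increasing in each rotational stiffness: stiffer
    restraint means a higher buckling load and a shorter effective column.
    """
    if EI <= 0 or L <= 0:
        raise DomainError(f"need EI > 0 and L > 0, got EI={EI}, L={L}")
    if min(k_rot_left, k_rot_right, k_lat) < 0:
        raise DomainError("spring stiffnesses must be non-negative")
    r0 = k_rot_left * L / EI
    rL = k_rot_right * L / EI
    t = k_lat * L**3 / EI
    if t == 0.0 and r0 == 0.0 and rL == 0.0:
        raise DomainError(
            "all three springs are zero: the column is a mechanism (P_cr = 0)"
        )

    f = lambda a: _characteristic_det(a, r0, rL, t)
    alphas = np.linspace(1e-4, alpha_max, n_scan)
    vals = np.array([f(a) for a in alphas])
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        raise SolveError(
            "no sign change of the characteristic determinant in "
            f"alpha in (0, {alpha_max:.3f}] for r0={r0:.3g}, rL={rL:.3g}, t={t:.3g}"
        )
    a_lo, a_hi = alphas[idx[0]], alphas[idx[0] + 1]
    alpha1 = brentq(f, a_lo, a_hi, xtol=xtol * alpha_max, rtol=1e-15)
    return math.pi / alpha1
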