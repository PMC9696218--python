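"""Persistence length from conformation ensembles via wormlike-chain statistics.

For a wormlike chain of contour length L, the mean square end-to-end
distance is

    <h^2> = 2 lp L [ 1 - (lp / L) (1 - e^{-L/lp}) ]

which is strictly increasing in lp at fixed L (from 0 toward the rigid-rod
limit L^2), so the persistence length can be recovered from an ensemble of
conformations by a monotone one-dimensional root find.

The module also provides a discrete wormlike-chain sampler as a synthetic
stand-in for simulation-derived helical axes: fixed bond length
ds = L / n_segments, successive bond angles drawn so that
<cos theta> = exp(-ds / lp) exactly (the polar angle follows the Boltzmann
distribution p(cos t) ~ exp(kappa cos t) with kappa solved from the Langevin
function; azimuth uniform), which makes the tangent autocorrelation decay as
exp(-s / lp) in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, SolveError

__all__ = [
    "ChainEnsemble",
    "eq_msee",
    "mean_square_end_to_end",
    "lp_from_msee",
    "estimate_lp",
    "sample_wlc",
]

#: Fraction of L^2 above which the ensemble is treated as a rigid rod and the
#: inversion returns the divergence sentinel ``math.inf``.
_ROD_FRACTION = 1.0 - 1e-12


@dataclass(frozen=True)
class ChainEnsemble:
    """An ordered set of chain conformations (each an (n, 3) coordinate array, m)."""

    conformations: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        confs = tuple(np.asarray(c, dtype=float) for c in self.conformations)
        if len(confs) == 0:
            raise DomainError("ensemble must contain at least one conformation")
        for i, c in enumerate(confs):
            if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 2:
                raise DomainError(
                    f"conformation {i} must be an (n >= 2, 3) array, got shape {c.shape}"
                )
        object.__setattr__(self, "conformations", confs)

    @property
    def contour_lengths(self) -> np.ndarray:
        """Per-conformation contour length measured along the polyline, m."""
        return np.array(
            [
                float(np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)))
                for c in self.conformations
            ]
        )

    @property
    def mean_contour_length(self) -> float:
        return float(self.contour_lengths.mean())

    def end_to_end(self) -> np.ndarray:
        """Per-conformation end-to-end distance, m."""
        return np.array(
            [float(np.linalg.norm(c[-1] - c[0])) for c in self.conformations]
        )

    def after_burn_in(self, burn_in: int) -> "ChainEnsemble":
        """Drop the first ``burn_in`` conformations (trajectory-ordered ensembles)."""
        if not 0 <= burn_in < len(self.conformations):
            raise DomainError(
                f"burn_in must be in [0, {len(self.conformations)}), got {burn_in}"
            )
        return ChainEnsemble(self.conformations[burn_in:])


def eq_msee(lp: float, L: float) -> float:
    """Forward wormlike-chain mean square end-to-end distance, m^2."""
    if lp <= 0 or L <= 0:
        raise DomainError(f"need lp > 0 and L > 0, got lp={lp}, L={L}")
    x = L / lp
    # 1 - (1 - e^{-x})/x, evaluated stably for small x.
    return 2.0 * lp * L * (1.0 + math.expm1(-x) / x)


def mean_square_end_to_end(ens: ChainEnsemble) -> float:
    """Ensemble average of the squared end-to-end distance, m^2."""
    return float(np.mean(ens.end_to_end() ** 2))


def lp_from_msee(msee: float, L: float, rtol: float = 1e-10) -> float:
    """Invert the wormlike-chain relation for lp at fixed contour length.

    Monotone bisection (Brent) on the strictly increasing forward relation.
    ``msee > L^2`` is outside the model and raises; msee within 1e-12 of L^2
    returns ``inf`` (rigid rod).
    """
    if L <= 0:
        raise DomainError(f"contour length must be positive, got {L}")
    if msee <= 0:
        raise DomainError(f"mean square end-to-end must be positive, got {msee}")
    if msee > L * L:
        raise DomainError(
            f"msee = {msee} exceeds L^2 = {L * L}: not a valid chain ensemble"
        )
    if msee >= _ROD_FRACTION * L * L:
        return math.inf

    g = lambda lp: eq_msee(lp, L) - msee
    lo = 1e-6 * L
    while g(lo) > 0:
        lo *= 0.1
        if lo < 1e-30 * L:
            raise SolveError(f"failed to bracket lp from below for msee={msee}, L={L}")
    hi = L
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e12 * L:
            raise SolveError(f"failed to bracket lp from above for msee={msee}, L={L}")
    return float(brentq(g, lo, hi, rtol=rtol))


def estimate_lp(
    ens: ChainEnsemble, mode: str = "ensemble", burn_in: int = 0
) -> float:
    """Persistence length of an ensemble, m.

    mode="ensemble" (default): invert the ensemble-mean square end-to-end
    distance at the ensemble-mean contour length.  mode="per_frame": invert
    each conformation separately and average the per-frame estimates (frames
    whose end-to-end reaches the rod limit contribute ``inf``).
    """
    if burn_in:
        ens = ens.after_burn_in(burn_in)
    if mode == "ensemble":
        return lp_from_msee(mean_square_end_to_end(ens), ens.mean_contour_length)
    if mode == "per_frame":
        Ls = ens.contour_lengths
        h2 = ens.end_to_end() ** 2
        return float(
            np.mean([lp_from_msee(float(h), float(L)) for h, L in zip(h2, Ls)])
        )
    raise DomainError(f"mode must be 'ensemble' or 'per_frame', got {mode!r}")


def _kappa_for_mean_cos(target: float) -> float:
    """Solve Langevin(kappa) = coth(kappa) - 1/kappa = target for kappa > 0."""
    if not 0 < target < 1:
        raise DomainError(f"mean cosine must be in (0, 1), got {target}")

    def langevin(k: float) -> float:
        if k < 1e-4:
            return k / 3.0 - k**3 / 45.0
        return 1.0 / math.tanh(k) - 1.0 / k

    lo, hi = 1e-12, 4.0
    while langevin(hi) < target:
        hi *= 2.0
        if hi > 1e18:
            raise SolveError(f"failed to bracket kappa for mean cos {target}")
    return float(brentq(lambda k: langevin(k) - target, lo, hi, rtol=1e-12))


def sample_wlc(
    lp: float,
    L: float,
    n_segments: int = 50,
    n_chains: int = 100,
    seed: int = 0,
) -> ChainEnsemble:
    """Sample discrete wormlike chains; seed-deterministic.

    Each chain has ``n_segments`` bonds of fixed length L/n_segments; the
    first tangent is uniform on the sphere, and each successive tangent is
    deflected by a polar angle drawn from the exponential-cosine density
    calibrated so that <cos theta> = exp(-ds/lp) exactly, with uniform
    azimuth about the previous tangent.
    """
    if lp <= 0 or L <= 0:
        raise DomainError(f"need lp > 0 and L > 0, got lp={lp}, L={L}")
    if n_segments < 10:
        raise DomainError(f"need n_segments >= 10, got {n_segments}")
    if n_chains < 1:
        raise DomainError(f"need n_chains >= 1, got {n_chains}")
    ds = L / n_segments
    mean_cos = math.exp(-ds / lp)
    kappa = _kappa_for_mean_cos(mean_cos)
    rng = np.random.default_rng(seed)

    # First tangents uniform on the unit sphere, one per chain.
    t = rng.normal(size=(n_chains, 3))
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    tangents = np.empty((n_chains, n_segments, 3))
    tangents[:, 0] = t
    # Inverse-CDF sampling of cos(theta) from p(c) ~ exp(kappa c) on [-1, 1].
    u = rng.random((n_chains, n_segments - 1))
    cos_t = 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    np.clip(cos_t, -1.0, 1.0, out=cos_t)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * math.pi, (n_chains, n_segments - 1))
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    for i in range(1, n_segments):
        t = tangents[:, i - 1]
        # Orthonormal frame around each tangent.
        a = np.where(np.abs(t[:, :1]) < 0.9, ex, ey)
        e1 = np.cross(t, a)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(t, e1)
        ct = cos_t[:, i - 1 : i]
        st = sin_t[:, i - 1 : i]
        ph = phi[:, i - 1 : i]
        tangents[:, i] = ct * t + st * (np.cos(ph) * e1 + np.sin(ph) * e2)
    coords = np.concatenate(
        [np.zeros((n_chains, 1, 3)), np.cumsum(tangents * ds, axis=1)], axis=1
    )
    return ChainEnsemble(tuple(coords))
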