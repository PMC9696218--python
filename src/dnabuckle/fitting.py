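"""Fit (mu, lcb) to persistence-length-vs-salt data; aggregate by constraint class.

A dataset is a set of (concentration, persistence length) measurements at a
fixed temperature and counterion valence.  The model curve lp(c; mu, lcb) is
the explicit buckling map evaluated at the electrostatic force scale of each
concentration; the two parameters are found by bounded nonlinear least
squares on the unweighted residuals, restarted from a deterministic Latin
hypercube of initial points because the sum-of-squares surface is a curved
valley (mu and lcb inflate the prediction together).

Goodness of fit is the coefficient of determination r^2 = 1 - SSR/TSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import DomainError
from .media_forces import DnaGeometry, Medium, reduced_electrostatic_force
from .persistence_map import lp_from_lcb

__all__ = [
    "ExperimentDataset",
    "FitResult",
    "ConstraintClassStats",
    "DEFAULT_BOUNDS",
    "fit_dataset",
    "goodness_of_fit",
    "aggregate_class",
    "model_curve",
]

CONSTRAINT_CLASSES = ("suspended", "fix_bead", "adsorbed")

#: Default fit bounds: mu in [0.3, 2.5] (brackets all classical end
#: conditions), lcb in [1, 30] nm (brackets the fitted experimental range).
DEFAULT_BOUNDS = ((0.3, 2.5), (1e-9, 30e-9))


@dataclass(frozen=True)
class ExperimentDataset:
    """(c, lp) records of one experiment, with its environmental metadata.

    records: sequence of (concentration mol/L, persistence length m) pairs;
        at least three, with strictly positive and unique concentrations.
    """

    records: tuple[tuple[float, float], ...]
    T: float = 298.0
    Z: int = 1
    constraint_class: str = "suspended"
    label: str = ""

    def __post_init__(self) -> None:
        recs = tuple((float(c), float(lp)) for c, lp in self.records)
        object.__setattr__(self, "records", recs)
        if len(recs) < 3:
            raise DomainError(f"need >= 3 records, got {len(recs)}")
        cs = [c for c, _ in recs]
        if any(c <= 0 for c in cs):
            raise DomainError("all concentrations must be strictly positive")
        if len(set(cs)) != len(cs):
            raise DomainError("concentrations must be unique")
        if any(lp <= 0 for _, lp in recs):
            raise DomainError("all persistence lengths must be strictly positive")
        if self.constraint_class not in CONSTRAINT_CLASSES:
            raise DomainError(
                f"constraint_class must be one of {CONSTRAINT_CLASSES}, "
                f"got {self.constraint_class!r}"
            )

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.records])

    @property
    def lp_values(self) -> np.ndarray:
        return np.array([lp for _, lp in self.records])


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters and diagnostics for one dataset.

    r2 is NaN when TSS = 0 (constant observations; r^2 undefined).
    """

    mu_hat: float
    lcb_hat: float
    r2: float
    ssr: float
    tss: float
    residuals: tuple[float, ...]
    converged: bool
    label: str = ""


@dataclass(frozen=True)
class ConstraintClassStats:
    """Mean and sample (n-1) standard deviation of fitted parameters in a class."""

    mu_mean: float
    mu_sd: float
    lcb_mean: float
    lcb_sd: float
    n: int


def model_curve(
    mu: float,
    lcb: float,
    concentrations: np.ndarray,
    T: float,
    Z: int,
    geom: DnaGeometry,
) -> np.ndarray:
    """Predicted lp (m) at each concentration for fixed (mu, lcb, T, Z)."""
    f = np.array(
        [
            reduced_electrostatic_force(Medium(c=float(c), Z=Z, T=T), geom)
            for c in np.atleast_1d(concentrations)
        ]
    )
    return np.atleast_1d(lp_from_lcb(mu, lcb, f, geom.R))


def goodness_of_fit(
    observed: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float, float]:
    """(r2, ssr, tss) with r2 = 1 - SSR/TSS; r2 is NaN when TSS = 0."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise DomainError(
            f"observed and predicted must have equal length >= 2, "
            f"got {obs.shape} and {pred.shape}"
        )
    ssr = float(np.sum((obs - pred) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    r2 = math.nan if tss == 0.0 else 1.0 - ssr / tss
    return r2, ssr, tss


def fit_dataset(
    data: ExperimentDataset,
    geom: DnaGeometry = DnaGeometry(),
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Fit (mu, lcb) to one dataset by multi-start bounded least squares.

    Starts are a Latin hypercube over the bounds, drawn from ``seed`` (lcb
    sampled log-uniformly); the optimizer works in (mu, lcb/nm) coordinates
    so both parameters are O(1), and residuals in nm.  The best of the
    converged starts is returned; if no start converges, ``converged`` is
    False and the least-bad point is reported with its diagnostics.
    """
    (mu_lo, mu_hi), (lcb_lo, lcb_hi) = bounds
    cs = data.concentrations
    obs_nm = data.lp_values * 1e9

    # Precompute the force scale once per concentration; the fit varies only
    # (mu, lcb).
    f = np.array(
        [
            reduced_electrostatic_force(Medium(c=float(c), Z=data.Z, T=data.T), geom)
            for c in cs
        ]
    )

    def residuals_nm(params: np.ndarray) -> np.ndarray:
        mu, lcb_nm = params
        pred = lp_from_lcb(mu, lcb_nm * 1e-9, f, geom.R) * 1e9
        return pred - obs_nm

    sampler = qmc.LatinHypercube(d=2, seed=seed)
    unit = sampler.random(n=n_starts)
    mu0 = mu_lo + unit[:, 0] * (mu_hi - mu_lo)
    lcb0_nm = np.exp(
        math.log(lcb_lo * 1e9)
        + unit[:, 1] * (math.log(lcb_hi * 1e9) - math.log(lcb_lo * 1e9))
    )

    lo = np.array([mu_lo, lcb_lo * 1e9])
    hi = np.array([mu_hi, lcb_hi * 1e9])
    best = None
    any_converged = False
    for m0, l0 in zip(mu0, lcb0_nm):
        sol = least_squares(
            residuals_nm,
            x0=np.clip([m0, l0], lo, hi),
            bounds=(lo, hi),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        cost = float(np.sum(sol.fun**2))
        if best is None or cost < best[0] - 1e-15 * max(1.0, best[0]):
            best = (cost, sol)
        any_converged = any_converged or sol.success

    _, sol = best
    mu_hat, lcb_hat_nm = sol.x
    pred = lp_from_lcb(mu_hat, lcb_hat_nm * 1e-9, f, geom.R)
    r2, ssr, tss = goodness_of_fit(data.lp_values, pred)
    return FitResult(
        mu_hat=float(mu_hat),
        lcb_hat=float(lcb_hat_nm * 1e-9),
        r2=r2,
        ssr=ssr,
        tss=tss,
        residuals=tuple(float(x) for x in (pred - data.lp_values)),
        converged=bool(any_converged),
        label=data.label,
    )


def _mu_lcb(item) -> tuple[float, float]:
    if isinstance(item, FitResult):
        return item.mu_hat, item.lcb_hat
    mu, lcb = item
    return float(mu), float(lcb)


def aggregate_class(fits: Iterable) -> ConstraintClassStats:
    """Mean and sample standard deviation of (mu, lcb) over a constraint class.

    Accepts ``FitResult`` objects or plain ``(mu, lcb)`` pairs.  The standard
    deviation uses the n-1 denominator, which is the convention the reported
    per-class aggregates follow.
    """
    pairs = [_mu_lcb(x) for x in fits]
    if len(pairs) < 2:
        raise DomainError(f"need >= 2 fits to aggregate, got {len(pairs)}")
    mus = np.array([p[0] for p in pairs])
    lcbs = np.array([p[1] for p in pairs])
    return ConstraintClassStats(
        mu_mean=float(mus.mean()),
        mu_sd=float(mus.std(ddof=1)),
        lcb_mean=float(lcbs.mean()),
        lcb_sd=float(lcbs.std(ddof=1)),
        n=len(pairs),
    )
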