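"""Synthetic persistence-length-vs-salt datasets generated from the model.

Stand-in for the literature measurement curves: the noiseless model curve
lp(c; mu, lcb) is multiplied by lognormal noise with a chosen coefficient of
variation (multiplicative noise matches the roughly proportional scatter of
persistence-length measurements across methods).  Seed-deterministic.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import DomainError
from .fitting import ExperimentDataset, model_curve
from .media_forces import DnaGeometry, Medium

__all__ = ["default_concentration_grid", "generate_synthetic_lp_dataset"]


def default_concentration_grid(n: int = 25) -> np.ndarray:
    """Log-spaced monovalent-salt grid over 0.001–4 mol/L, the modeled coverage."""
    return np.geomspace(0.001, 4.0, n)


def generate_synthetic_lp_dataset(
    mu_true: float,
    lcb_true: float,
    medium_template: Medium,
    c_grid: Sequence[float],
    noise_cv: float = 0.05,
    seed: int = 0,
    geom: DnaGeometry = DnaGeometry(),
    constraint_class: str = "suspended",
    label: str = "synthetic",
) -> ExperimentDataset:
    """Model-generated (c, lp) dataset with multiplicative lognormal noise.

    The lognormal factor has unit mean and coefficient of variation
    ``noise_cv`` (sigma^2 = ln(1 + cv^2), mean-corrected), so noise_cv = 0
    returns the exact model curve.
    """
    if noise_cv < 0:
        raise DomainError(f"noise_cv must be non-negative, got {noise_cv}")
    cs = np.asarray(c_grid, dtype=float)
    lp = model_curve(mu_true, lcb_true, cs, medium_template.T, medium_template.Z, geom)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=cs.size)
        lp = lp * factors
    return ExperimentDataset(
        records=tuple(zip(cs.tolist(), lp.tolist())),
        T=medium_template.T,
        Z=medium_template.Z,
        constraint_class=constraint_class,
        label=label,
    )
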