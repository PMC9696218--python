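"""Published per-experiment fitted parameters, at printed precision.

These are the reference values of the buckling model fitted to literature
persistence-length-vs-salt curves: one row per experiment (method, constraint
class, temperature, salt, fitted effective length factor mu, fitted critical
buckling length lcb, goodness of fit r^2), plus helpers selecting the rows by
constraint class.  They serve as fixtures for the aggregation and prediction
workflows; the underlying raw (c, lp) measurements belong to the original
literature and are not shipped.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceExperiment", "REFERENCE_EXPERIMENTS", "CLASS_AGGREGATES", "rows_for_class"]


@dataclass(frozen=True)
class ReferenceExperiment:
    method: str
    constraint_class: str  # suspended | fix_bead | adsorbed
    T: float  # K
    salt: str
    c_range: tuple[float, float]  # mol/L
    contour_bp: int
    lp_range_nm: tuple[float, float]
    mu: float
    lcb_nm: float
    r2: float


REFERENCE_EXPERIMENTS: tuple[ReferenceExperiment, ...] = (
    ReferenceExperiment("Rayleigh light scattering", "suspended", 293.0, "NaH2PO4",
              (0.005, 3.0), 39000, (38.0, 78.0), 0.668, 9.16, 0.893),
    ReferenceExperiment("Linear dichroism", "suspended", 298.0, "NaCl",
              (0.002, 1.0), 39000, (40.2, 66.9), 1.256, 4.18, 0.652),
    ReferenceExperiment("Flow birefringence", "suspended", 298.0, "NaCl",
              (0.002, 1.0), 39000, (39.9, 72.3), 1.065, 5.14, 0.815),
    ReferenceExperiment("Dynamic light scattering", "suspended", 298.0, "NaCl",
              (0.005, 4.0), 6594, (32.0, 91.4), 1.095, 5.31, 0.761),
    ReferenceExperiment("Optical tweezers", "fix_bead", 298.0, "NaCl",
              (0.00186, 0.586), 48500, (45.1, 96.3), 0.635, 9.64, 0.511),
    ReferenceExperiment("Tethered-particle method", "fix_bead", 298.0, "NaCl",
              (0.015, 3.33), 2060, (34.9, 54.7), 0.835, 6.52, 0.824),
    ReferenceExperiment("Tethered-particle method", "fix_bead", 298.0, "NaCl",
              (0.015, 3.33), 1201, (31.3, 52.2), 0.686, 7.88, 0.911),
    ReferenceExperiment("Tethered-particle method", "fix_bead", 298.0, "MgCl2",
              (0.003, 0.104), 2060, (37.2, 50.1), 0.736, 8.95, 0.614),
    ReferenceExperiment("Tethered-particle method", "fix_bead", 298.0, "MgCl2",
              (0.003, 0.104), 1201, (36.7, 46.1), 0.700, 9.18, 0.624),
    ReferenceExperiment("Electron microscopy", "adsorbed", 298.0, "NaCl",
              (0.03, 0.5), 4800, (54.5, 145.6), 0.489, 15.83, 0.404),
)

#: Published per-class aggregates (mean, sample SD), at printed precision.
CLASS_AGGREGATES = {
    "suspended": {"mu": (1.021, 0.250), "lcb_nm": (5.95, 2.20)},
    "fix_bead": {"mu": (0.718, 0.075), "lcb_nm": (8.43, 1.25)},
}


def rows_for_class(constraint_class: str) -> tuple[ReferenceExperiment, ...]:
    """All reference rows belonging to one constraint class."""
    rows = tuple(r for r in REFERENCE_EXPERIMENTS if r.constraint_class == constraint_class)
    if not rows:
        raise KeyError(f"unknown constraint class {constraint_class!r}")
    return rows
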