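"""Plain-text file formats and run configuration.

Dataset files are delimited text (comma or tab) with header
``concentration_M, lp_nm`` and a sidecar metadata block of ``# key = value``
comment lines (temperature_K, valence, constraint_class, label).
Conformation files are multi-record XYZ-style text: a count line, then
``x y z`` rows in nanometers, one block per conformation.  Run configuration
is flat YAML with strict key validation.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import DomainError
from .fitting import DEFAULT_BOUNDS, ExperimentDataset, FitResult
from .wlc_ensemble import ChainEnsemble

__all__ = [
    "MalformedFileError",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "read_conformations",
    "write_conformations",
    "write_fit_result",
    "read_config",
]


class MalformedFileError(ValueError):
    """A data file violates the expected format; message names file and line."""


_META_KEYS = {"temperature_K", "valence", "constraint_class", "label"}


def read_dataset(path: str | Path) -> ExperimentDataset:
    """Read a (concentration, persistence length) dataset file.

    Accepts comma- or tab-delimited columns with headers ``concentration_M``
    and ``lp_nm`` (lengths may alternatively be given as ``lp_m``).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[float, float]] = []
    delim = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        if delim is None:
            delim = "\t" if "\t" in line else ","
        fields = [f.strip() for f in line.split(delim)]
        if header is None:
            header = fields
            if "concentration_M" not in header or not (
                "lp_nm" in header or "lp_m" in header
            ):
                raise MalformedFileError(
                    f"{path}:{lineno}: header must contain 'concentration_M' and "
                    f"'lp_nm' (or 'lp_m'), got {header}"
                )
            continue
        if len(fields) != len(header):
            raise MalformedFileError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        try:
            rec = {k: float(v) for k, v in zip(header, fields)}
        except ValueError as exc:
            raise MalformedFileError(f"{path}:{lineno}: {exc}") from None
        lp_m = rec["lp_m"] if "lp_m" in rec else rec["lp_nm"] * 1e-9
        rows.append((rec["concentration_M"], lp_m))
    if header is None or not rows:
        raise MalformedFileError(f"{path}: no data rows found")
    unknown = set(meta) - _META_KEYS
    if unknown:
        raise MalformedFileError(
            f"{path}: unknown metadata key(s): {', '.join(sorted(unknown))}"
        )
    try:
        return ExperimentDataset(
            records=tuple(rows),
            T=float(meta.get("temperature_K", 298.0)),
            Z=int(meta.get("valence", 1)),
            constraint_class=meta.get("constraint_class", "suspended"),
            label=meta.get("label", path.stem),
        )
    except DomainError as exc:
        raise MalformedFileError(f"{path}: {exc}") from exc


def write_dataset(data: ExperimentDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# temperature_K = {data.T:g}\n")
        fh.write(f"# valence = {data.Z}\n")
        fh.write(f"# constraint_class = {data.constraint_class}\n")
        if data.label:
            fh.write(f"# label = {data.label}\n")
        fh.write("concentration_M,lp_nm\n")
        for c, lp in data.records:
            fh.write(f"{c:.9g},{lp * 1e9:.9g}\n")


def read_conformations(path: str | Path) -> ChainEnsemble:
    """Read a multi-record XYZ-style conformation file (coordinates in nm)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    confs: list[np.ndarray] = []
    i = 0
    lineno = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        lineno = i + 1
        i += 1
        if not line:
            continue
        try:
            count = int(line)
        except ValueError:
            raise MalformedFileError(
                f"{path}:{lineno}: expected a point count, got {line!r}"
            ) from None
        if count < 2:
            raise MalformedFileError(f"{path}:{lineno}: point count must be >= 2")
        block = []
        for j in range(count):
            if i >= n_lines:
                raise MalformedFileError(
                    f"{path}:{lineno}: block declares {count} points but file ended"
                )
            parts = lines[i].split()
            if len(parts) != 3:
                raise MalformedFileError(
                    f"{path}:{i + 1}: expected 'x y z', got {lines[i]!r}"
                )
            try:
                block.append([float(p) for p in parts])
            except ValueError as exc:
                raise MalformedFileError(f"{path}:{i + 1}: {exc}") from None
            i += 1
        confs.append(np.array(block) * 1e-9)
    if not confs:
        raise MalformedFileError(f"{path}: no conformations found")
    return ChainEnsemble(tuple(confs))


def write_conformations(ens: ChainEnsemble, path: str | Path) -> None:
    """Write conformations as XYZ-style text in nm, 9 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        for conf in ens.conformations:
            fh.write(f"{conf.shape[0]}\n")
            for x, y, z in conf * 1e9:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def write_fit_result(result: FitResult, path_or_stream) -> None:
    """Emit a fit result as a flat key = value record."""
    own = isinstance(path_or_stream, (str, Path))
    fh = open(path_or_stream, "w") if own else path_or_stream
    try:
        if result.label:
            fh.write(f"label = {result.label}\n")
        fh.write(f"mu_hat = {result.mu_hat:.6g}\n")
        fh.write(f"lcb_hat_nm = {result.lcb_hat * 1e9:.6g}\n")
        r2 = "nan" if math.isnan(result.r2) else f"{result.r2:.6g}"
        fh.write(f"r2 = {r2}\n")
        fh.write(f"ssr_nm2 = {result.ssr * 1e18:.6g}\n")
        fh.write(f"tss_nm2 = {result.tss * 1e18:.6g}\n")
        fh.write(f"converged = {str(result.converged).lower()}\n")
    finally:
        if own:
            fh.close()


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (flat YAML on disk)."""

    R_nm: float = 1.0
    b_nm: float = 0.17
    valence: int = 1
    temperature_K: float = 298.0
    mu_bounds: tuple[float, float] = DEFAULT_BOUNDS[0]
    lcb_bounds_nm: tuple[float, float] = (
        DEFAULT_BOUNDS[1][0] * 1e9,
        DEFAULT_BOUNDS[1][1] * 1e9,
    )
    n_starts: int = 8
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.R_nm <= 0 or self.b_nm <= 0:
            raise DomainError("R_nm and b_nm must be positive")
        if self.n_starts < 1:
            raise DomainError("n_starts must be >= 1")


_CONFIG_KEYS = set(RunConfig.__dataclass_fields__)


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise MalformedFileError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise MalformedFileError(
            f"{path}: unknown config key(s): {', '.join(sorted(unknown))}"
        )
    for key in ("mu_bounds", "lcb_bounds_nm"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
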