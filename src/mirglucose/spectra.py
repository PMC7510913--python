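"""Wavenumber-indexed spectra: data model, absorbance transform, CSV I/O.

The pipeline's universal currency is absorbance sampled on a shared
wavenumber grid.  Raw measurements arrive as paired intensities (sample ``I``
and reference ``I0``) and are converted to decadic absorbance
``A = -log10(I / I0)``.  Sets of spectra carry per-sample metadata: a sample
ID, the individual (animal) the sample came from, the measurement mode and
the reference glucose concentration in mg/dL.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MGDL_PER_MMOL",
    "mgdl_to_mmol",
    "mmol_to_mgdl",
    "WavenumberGrid",
    "Spectrum",
    "SpectraSet",
    "default_grid",
    "compute_absorbance",
    "crop",
    "read_set",
    "write_set",
    "SpectraError",
]

#: Molar mass of glucose (180.16 g/mol) expressed as mg/dL per mmol/L.
MGDL_PER_MMOL = 18.016


def mgdl_to_mmol(x):
    """Convert a glucose concentration from mg/dL to mmol/L."""
    return np.asarray(x, dtype=float) / MGDL_PER_MMOL


def mmol_to_mgdl(x):
    """Convert a glucose concentration from mmol/L to mg/dL."""
    return np.asarray(x, dtype=float) * MGDL_PER_MMOL


class SpectraError(ValueError):
    """Raised for invalid spectra, grids or malformed spectra files."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly monotonic wavenumber axis in cm^-1.

    Acquisition sweeps run high-to-low (1200 -> 925 cm^-1), so the default
    orientation is descending; every operation in the package is
    orientation-agnostic.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise SpectraError("grid needs at least 2 wavenumbers")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise SpectraError("wavenumbers must be finite and positive")
        d = np.diff(v)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraError("wavenumber grid must be strictly monotonic")

    @property
    def orientation(self) -> str:
        return "ascending" if self.values[1] > self.values[0] else "descending"

    @property
    def spacing(self) -> float:
        """Signed mean step in cm^-1 (negative for descending grids)."""
        return float(np.mean(np.diff(self.values)))

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash(self.values.tobytes())


def default_grid() -> WavenumberGrid:
    """The acquisition grid: 1200 -> 925 cm^-1, 1 cm^-1 steps (276 points)."""
    return WavenumberGrid(np.arange(1200.0, 924.0, -1.0))


@dataclass(frozen=True)
class Spectrum:
    """One spectrum on a wavenumber grid, either intensities or absorbance."""

    grid: WavenumberGrid
    values: np.ndarray
    kind: str = "absorbance"  # {"intensity", "absorbance"}
    sample_id: str = ""
    individual_id: str = ""
    mode: str = ""  # {"transmission", "atr", ""}
    reference_glucose: Optional[float] = None  # mg/dL

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.kind not in ("intensity", "absorbance"):
            raise SpectraError(f"unknown spectrum kind {self.kind!r}")
        if v.shape != (len(self.grid),):
            raise SpectraError("spectrum length does not match its grid")
        if not np.all(np.isfinite(v)):
            raise SpectraError("spectrum values must be finite")
        if self.kind == "intensity" and np.any(v <= 0):
            raise SpectraError("intensity spectra must be strictly positive")


@dataclass(frozen=True)
class SpectraSet:
    """A samples x wavenumbers absorbance table with sample metadata.

    ``glucose`` holds reference concentrations in mg/dL (NaN = missing);
    ``groups`` holds the individual ID of each sample, used by the grouped
    validation designs so no individual leaks across a train/validation split.
    """

    grid: WavenumberGrid
    matrix: np.ndarray
    glucose: np.ndarray
    groups: np.ndarray
    mode: str = ""
    sample_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        g = np.asarray(self.glucose, dtype=float)
        grp = np.asarray(self.groups, dtype=object)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "glucose", g)
        object.__setattr__(self, "groups", grp)
        if m.shape[1] != len(self.grid):
            raise SpectraError("matrix columns do not match the grid")
        if not (m.shape[0] == g.size == grp.size):
            raise SpectraError("matrix rows, glucose and groups must align")
        if not np.all(np.isfinite(m)):
            raise SpectraError("absorbance matrix must be finite")
        sid = self.sample_ids
        if sid is None:
            sid = np.array([f"s{i:03d}" for i in range(m.shape[0])], dtype=object)
        else:
            sid = np.asarray(sid, dtype=object)
            if sid.size != m.shape[0]:
                raise SpectraError("sample_ids do not match matrix rows")
            if len(set(sid)) != sid.size:
                raise SpectraError("duplicate sample IDs")
        object.__setattr__(self, "sample_ids", sid)

    @property
    def n_samples(self) -> int:
        return int(self.matrix.shape[0])

    def subset(self, index) -> "SpectraSet":
        """Row-subset by boolean mask or integer index array."""
        idx = np.asarray(index)
        return SpectraSet(
            grid=self.grid,
            matrix=self.matrix[idx],
            glucose=self.glucose[idx],
            groups=self.groups[idx],
            mode=self.mode,
            sample_ids=self.sample_ids[idx],
        )

    def individuals(self) -> list:
        """Distinct individual IDs in first-appearance order."""
        seen: dict = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)


def compute_absorbance(sample: Spectrum, reference: Spectrum) -> Spectrum:
    """Decadic absorbance A = -log10(I / I0) from paired intensity spectra.

    Metadata is carried over from the sample spectrum.
    """
    if sample.kind != "intensity" or reference.kind != "intensity":
        raise SpectraError("compute_absorbance needs two intensity spectra")
    if sample.grid != reference.grid:
        raise SpectraError("sample and reference grids differ")
    a = -np.log10(sample.values / reference.values)
    return replace(sample, values=a, kind="absorbance")


def crop(obj, lo: float, hi: float):
    """Restrict a Spectrum or SpectraSet to wavenumbers lo <= nu <= hi."""
    if lo >= hi:
        raise SpectraError(f"crop bounds must satisfy lo < hi, got {lo} >= {hi}")
    mask = (obj.grid.values >= lo) & (obj.grid.values <= hi)
    if not mask.any():
        raise SpectraError(f"crop [{lo}, {hi}] leaves no grid points")
    new_grid = WavenumberGrid(obj.grid.values[mask])
    if isinstance(obj, Spectrum):
        return replace(obj, grid=new_grid, values=obj.values[mask])
    if isinstance(obj, SpectraSet):
        return SpectraSet(
            grid=new_grid,
            matrix=obj.matrix[:, mask],
            glucose=obj.glucose,
            groups=obj.groups,
            mode=obj.mode,
            sample_ids=obj.sample_ids,
        )
    raise TypeError(f"cannot crop object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# CSV layout
#
# spectra.csv:  first column ``sample_id``, one column per grid wavenumber
#               with the wavenumber as header; absorbance values.
# metadata.csv: columns ``sample_id, individual_id, mode, glucose_mgdl``;
#               glucose may be empty (missing reference value).
# ---------------------------------------------------------------------------

SPECTRA_FILE = "spectra.csv"
METADATA_FILE = "metadata.csv"


def write_set(sset: SpectraSet, out_dir: str) -> tuple:
    """Write a SpectraSet as the spectra/metadata CSV pair; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    spectra_path = os.path.join(out_dir, SPECTRA_FILE)
    meta_path = os.path.join(out_dir, METADATA_FILE)
    cols = [f"{v:.12g}" for v in sset.grid.values]
    df = pd.DataFrame(sset.matrix, columns=cols)
    df.insert(0, "sample_id", sset.sample_ids)
    df.to_csv(spectra_path, index=False, float_format="%.12g")
    meta = pd.DataFrame(
        {
            "sample_id": sset.sample_ids,
            "individual_id": sset.groups,
            "mode": sset.mode,
            "glucose_mgdl": sset.glucose,
        }
    )
    meta.to_csv(meta_path, index=False, float_format="%.12g")
    return spectra_path, meta_path


def read_set(spectra_path: str, metadata_path: str) -> SpectraSet:
    """Read the spectra/metadata CSV pair back into a SpectraSet."""
    try:
        df = pd.read_csv(spectra_path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraError(f"malformed spectra file: {exc}") from exc
    if df.columns[0] != "sample_id":
        raise SpectraError("spectra file must start with a sample_id column")
    try:
        wn = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectraError(f"non-numeric wavenumber header: {exc}") from exc
    grid = WavenumberGrid(wn)  # enforces monotonicity/positivity
    sample_ids = df["sample_id"].astype(str).to_numpy(dtype=object)
    if len(set(sample_ids)) != sample_ids.size:
        raise SpectraError("duplicate sample IDs in spectra file")
    matrix = df.iloc[:, 1:].to_numpy(dtype=float)

    meta = pd.read_csv(metadata_path)
    required = {"sample_id", "individual_id", "mode", "glucose_mgdl"}
    missing = required - set(meta.columns)
    if missing:
        raise SpectraError(f"metadata is missing columns: {sorted(missing)}")
    meta = meta.set_index(meta["sample_id"].astype(str))
    try:
        meta = meta.loc[list(sample_ids)]
    except KeyError as exc:
        raise SpectraError(f"metadata missing sample IDs: {exc}") from exc
    modes = set(meta["mode"].astype(str))
    if len(modes) != 1:
        raise SpectraError(f"mixed measurement modes in one set: {sorted(modes)}")
    return SpectraSet(
        grid=grid,
        matrix=matrix,
        glucose=meta["glucose_mgdl"].to_numpy(dtype=float),
        groups=meta["individual_id"].astype(str).to_numpy(dtype=object),
        mode=modes.pop(),
        sample_ids=sample_ids,
    )
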