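"""Spectral preprocessing operators and their grid enumeration.

Every operator is row-wise (acts on one spectrum at a time and does not
depend on the training set); only the final mean-centering learns statistics,
and those are always computed on training rows alone.  The pipeline order is
fixed: filter -> derivative -> baseline correction -> normalisation ->
mean-centering.

The Savitzky-Golay weights are derived internally by solving the local
least-squares polynomial fit (no table lookup), with shrink-window asymmetric
fits at the edges so polynomials up to the fitting order are reproduced
exactly everywhere.  The Fourier filter is a low-pass with a 4-term
Blackman-Harris taper: the signal is evenly (symmetrically) extended to
suppress wrap-around artefacts, frequency bins up to the cutoff pass
unchanged, and the taper descends over a transition band of
``cutoff * (multiplier - 1)`` bins.  Cutoffs count one-sided frequency bins
of the raw (unextended) signal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .spectra import SpectraSet, SpectraError, WavenumberGrid

__all__ = [
    "PreprocessSpec",
    "FittedPreprocessor",
    "PreprocessError",
    "savgol_coefficients",
    "savitzky_golay",
    "fourier_filter",
    "derivative",
    "baseline_linear",
    "normalise_unit",
    "row_transform",
    "fit_apply",
    "apply",
    "enumerate_pipelines",
    "DEFAULT_GRID_OPTIONS",
]


class PreprocessError(ValueError):
    """Raised for invalid preprocessing parameters or unfitted application."""


# ---------------------------------------------------------------------------
# Savitzky-Golay
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def savgol_coefficients(width: int, order: int, deriv: int = 0) -> np.ndarray:
    """Central convolution weights of the SG filter, derived by least squares.

    For the window offsets j = -h..h the local polynomial fit is
    ``a = (X^T X)^-1 X^T y`` with ``X[j, k] = j**k``; the deriv-th derivative
    at the window centre is ``deriv! * a_deriv``, so the weight vector is
    ``deriv! *`` the deriv-th row of the pseudo-inverse of X.
    """
    if width < 3 or width % 2 == 0:
        raise PreprocessError("SG width must be odd and >= 3")
    if not 0 <= order < width:
        raise PreprocessError("SG order must satisfy 0 <= order < width")
    if deriv > order:
        raise PreprocessError("SG derivative order cannot exceed the poly order")
    h = width // 2
    offsets = np.arange(-h, h + 1, dtype=float)
    design = np.vander(offsets, order + 1, increasing=True)
    pinv = np.linalg.pinv(design)
    return math.factorial(deriv) * pinv[deriv]


def _sg_edge(values: np.ndarray, i: int, h: int, order: int, deriv: int) -> float:
    """Shrink-window fit: same-order polynomial on the available asymmetric
    window, derivative evaluated at point i."""
    lo, hi = max(0, i - h), min(values.shape[0] - 1, i + h)
    offsets = np.arange(lo - i, hi - i + 1, dtype=float)
    design = np.vander(offsets, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, values[lo : hi + 1], rcond=None)
    return math.factorial(deriv) * coef[deriv]


def savitzky_golay(
    values: np.ndarray,
    width: int,
    order: int,
    deriv: int = 0,
    spacing: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / differentiation along the last axis.

    ``spacing`` is the (signed) grid step; derivatives are returned per unit
    of the physical axis, i.e. divided by ``spacing**deriv``.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[-1]
    if width > n:
        raise PreprocessError(f"SG width {width} exceeds spectrum length {n}")
    coeffs = savgol_coefficients(width, order, deriv)
    h = width // 2
    out = np.empty_like(v)
    windows = sliding_window_view(v, width, axis=-1)
    out[..., h : n - h] = windows @ coeffs
    flat = v.reshape(-1, n)
    oflat = out.reshape(-1, n)
    for r in range(flat.shape[0]):
        for i in list(range(h)) + list(range(n - h, n)):
            oflat[r, i] = _sg_edge(flat[r], i, h, order, deriv)
    if deriv:
        out = out / spacing**deriv
    return out.reshape(v.shape)


# ---------------------------------------------------------------------------
# Fourier low-pass with Blackman-Harris taper
# ---------------------------------------------------------------------------

_BH4 = (0.35875, 0.48829, 0.14128, 0.01168)  # 4-term Blackman-Harris


def _bh_taper(u: np.ndarray) -> np.ndarray:
    """Descending half of the 4-term Blackman-Harris window on u in [0, 1]:
    1 at u = 0, ~6e-5 at u = 1."""
    a0, a1, a2, a3 = _BH4
    return (
        a0
        + a1 * np.cos(np.pi * u)
        + a2 * np.cos(2.0 * np.pi * u)
        + a3 * np.cos(3.0 * np.pi * u)
    )


def fourier_filter(
    values: np.ndarray, cutoff: int = 28, multiplier: float = 1.3
) -> np.ndarray:
    """Low-pass Fourier filter along the last axis.

    Bins up to ``cutoff`` (one-sided, counted on the raw signal) pass
    unchanged; the Blackman-Harris taper attenuates bins in the transition
    band ``(cutoff, cutoff * multiplier]``; higher bins are removed.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[-1]
    if cutoff < 1:
        raise PreprocessError("Fourier cutoff must be >= 1")
    if multiplier <= 0:
        raise PreprocessError("Fourier multiplier must be positive")
    if cutoff >= n / 2:
        raise PreprocessError(
            f"Fourier cutoff {cutoff} reaches the Nyquist index of a "
            f"{n}-point spectrum"
        )
    ext = np.concatenate([v, v[..., ::-1]], axis=-1)  # even extension, 2n
    spec = np.fft.rfft(ext, axis=-1)
    # extended bin k corresponds to raw-signal frequency k / 2
    f_raw = np.arange(spec.shape[-1], dtype=float) / 2.0
    hi = cutoff * multiplier
    gain = np.zeros_like(f_raw)
    gain[f_raw <= cutoff] = 1.0
    trans = (f_raw > cutoff) & (f_raw <= hi)
    if hi > cutoff:
        gain[trans] = _bh_taper((f_raw[trans] - cutoff) / (hi - cutoff))
    filtered = np.fft.irfft(spec * gain, n=2 * n, axis=-1)[..., :n]
    return filtered


# ---------------------------------------------------------------------------
# Remaining row-wise operators
# ---------------------------------------------------------------------------


def derivative(
    values: np.ndarray, order: int, spacing: float = 1.0, width: int = 9
) -> np.ndarray:
    """Spectral derivative via SG differentiation (width 9, poly order
    max(2, order)), scaled by the grid spacing."""
    if order not in (1, 2):
        raise PreprocessError("derivative order must be 1 or 2")
    return savitzky_golay(values, width, max(2, order), deriv=order, spacing=spacing)


def baseline_linear(values: np.ndarray) -> np.ndarray:
    """Subtract the straight line through the first and last point of each
    spectrum; the endpoints map exactly to zero."""
    v = np.asarray(values, dtype=float)
    n = v.shape[-1]
    if n < 2:
        raise PreprocessError("baseline correction needs >= 2 points")
    t = np.linspace(0.0, 1.0, n)
    first = v[..., :1]
    last = v[..., -1:]
    return v - (first + (last - first) * t)


def normalise_unit(values: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit Euclidean norm."""
    v = np.asarray(values, dtype=float)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise PreprocessError("cannot normalise an all-zero spectrum")
    return v / norm


# ---------------------------------------------------------------------------
# Declarative pipelines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PreprocessSpec:
    """Ordered preprocessing choices: filter -> derivative -> baseline ->
    normalisation (mean-centering is always applied afterwards)."""

    filter: str = "none"  # {"none", "sg", "fourier"}
    sg_width: int = 9
    sg_order: int = 1
    fourier_cutoff: int = 28
    fourier_multiplier: float = 1.3
    derivative: int = 0  # {0, 1, 2}
    baseline: str = "none"  # {"none", "linear"}
    normalisation: str = "none"  # {"none", "unit"}

    def __post_init__(self):
        if self.filter not in ("none", "sg", "fourier"):
            raise PreprocessError(f"unknown filter {self.filter!r}")
        if self.filter == "sg":
            if self.sg_width < 3 or self.sg_width % 2 == 0:
                raise PreprocessError("sg_width must be odd and >= 3")
            if not 0 <= self.sg_order < self.sg_width:
                raise PreprocessError("sg_order must satisfy 0 <= order < width")
        if self.filter == "fourier":
            if self.fourier_cutoff < 1:
                raise PreprocessError("fourier_cutoff must be >= 1")
            if self.fourier_multiplier <= 0:
                raise PreprocessError("fourier_multiplier must be > 0")
        if self.derivative not in (0, 1, 2):
            raise PreprocessError("derivative must be 0, 1 or 2")
        if self.baseline not in ("none", "linear"):
            raise PreprocessError(f"unknown baseline {self.baseline!r}")
        if self.normalisation not in ("none", "unit"):
            raise PreprocessError(f"unknown normalisation {self.normalisation!r}")

    @property
    def n_active_steps(self) -> int:
        """Number of non-trivial steps; the grid-search parsimony tie-break."""
        return sum(
            [
                self.filter != "none",
                self.derivative != 0,
                self.baseline != "none",
                self.normalisation != "none",
            ]
        )

    @property
    def label(self) -> str:
        parts = []
        if self.filter == "sg":
            parts.append(f"sg({self.sg_width},{self.sg_order})")
        elif self.filter == "fourier":
            parts.append(
                f"fourier({self.fourier_cutoff},{self.fourier_multiplier:g})"
            )
        if self.derivative:
            parts.append(f"d{self.derivative}")
        if self.baseline != "none":
            parts.append(self.baseline)
        if self.normalisation != "none":
            parts.append(self.normalisation)
        return "+".join(parts) if parts else "raw"

    def to_dict(self) -> dict:
        return {
            "filter": self.filter,
            "sg_width": self.sg_width,
            "sg_order": self.sg_order,
            "fourier_cutoff": self.fourier_cutoff,
            "fourier_multiplier": self.fourier_multiplier,
            "derivative": self.derivative,
            "baseline": self.baseline,
            "normalisation": self.normalisation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        known = set(cls().to_dict())
        unknown = set(d) - known
        if unknown:
            raise PreprocessError(f"unknown preprocessing keys: {sorted(unknown)}")
        return cls(**d)


def row_transform(
    spec: PreprocessSpec, matrix: np.ndarray, spacing: float = 1.0
) -> np.ndarray:
    """Apply the row-wise operators (everything except centering) to a
    samples x wavenumbers matrix."""
    x = np.asarray(matrix, dtype=float)
    if spec.filter == "sg":
        x = savitzky_golay(x, spec.sg_width, spec.sg_order)
    elif spec.filter == "fourier":
        x = fourier_filter(x, spec.fourier_cutoff, spec.fourier_multiplier)
    if spec.derivative:
        x = derivative(x, spec.derivative, spacing=spacing)
    if spec.baseline == "linear":
        x = baseline_linear(x)
    if spec.normalisation == "unit":
        x = normalise_unit(x)
    return x


@dataclass(frozen=True)
class FittedPreprocessor:
    """A PreprocessSpec plus the training-set statistics it learned."""

    spec: PreprocessSpec
    grid: WavenumberGrid
    column_means: np.ndarray
    y_mean: float

    def transform(self, sset: SpectraSet) -> np.ndarray:
        """Row operators + subtraction of the training column means."""
        return apply(self, sset)


def fit_apply(spec: PreprocessSpec, train: SpectraSet):
    """Fit centering statistics on the training set and return
    ``(FittedPreprocessor, centered training matrix)``.

    Training requires reference glucose for every sample; sets with missing
    values are rejected.
    """
    if np.any(~np.isfinite(train.glucose)):
        raise PreprocessError(
            "training set has samples without reference glucose"
        )
    t = row_transform(spec, train.matrix, train.grid.spacing)
    means = t.mean(axis=0)
    fp = FittedPreprocessor(
        spec=spec,
        grid=train.grid,
        column_means=means,
        y_mean=float(train.glucose.mean()),
    )
    return fp, t - means


def apply(fp: FittedPreprocessor, other: SpectraSet) -> np.ndarray:
    """Apply a fitted preprocessor to another set on the same grid."""
    if not isinstance(fp, FittedPreprocessor):
        raise PreprocessError("preprocessor must be fitted before application")
    if other.grid != fp.grid:
        raise PreprocessError("grid mismatch between preprocessor and data")
    t = row_transform(fp.spec, other.matrix, other.grid.spacing)
    return t - fp.column_means


#: The default model-selection grid: 3 filters x 3 derivatives x 2 baselines
#: x 2 normalisations = 36 pipelines.
DEFAULT_GRID_OPTIONS: Dict[str, list] = {
    "filters": [
        {"filter": "none"},
        {"filter": "sg", "sg_width": 9, "sg_order": 1},
        {"filter": "fourier", "fourier_cutoff": 28, "fourier_multiplier": 1.3},
    ],
    "derivatives": [0, 1, 2],
    "baselines": ["none", "linear"],
    "normalisations": ["none", "unit"],
}


def enumerate_pipelines(
    filters: Optional[Sequence[dict]] = None,
    derivatives: Optional[Sequence[int]] = None,
    baselines: Optional[Sequence[str]] = None,
    normalisations: Optional[Sequence[str]] = None,
) -> List[PreprocessSpec]:
    """Cartesian product of preprocessing options, filter-major order."""
    filters = DEFAULT_GRID_OPTIONS["filters"] if filters is None else filters
    derivatives = (
        DEFAULT_GRID_OPTIONS["derivatives"] if derivatives is None else derivatives
    )
    baselines = DEFAULT_GRID_OPTIONS["baselines"] if baselines is None else baselines
    normalisations = (
        DEFAULT_GRID_OPTIONS["normalisations"]
        if normalisations is None
        else normalisations
    )
    for opts, name in (
        (filters, "filters"),
        (derivatives, "derivatives"),
        (baselines, "baselines"),
        (normalisations, "normalisations"),
    ):
        if len(opts) == 0:
            raise PreprocessError(f"empty option list for {name}")
    specs = []
    for f, d, b, n in itertools.product(filters, derivatives, baselines, normalisations):
        specs.append(
            PreprocessSpec(derivative=d, baseline=b, normalisation=n, **f)
        )
    return specs
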