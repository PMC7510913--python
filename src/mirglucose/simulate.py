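"""Forward simulation of mid-IR glucose spectra in biofluid-like matrices.

Transmission spectra follow Beer-Lambert: A(nu) = sum_c eps_c(nu) * conc_c * L
with a fixed pathlength L (200 um fibre gap by default).  ATR spectra replace
L by N * d_e(nu), where N is the reflection count on the internal reflection
element (11 by default) and d_e is an effective pathlength per reflection that
grows with wavelength, d_e(nu) = penetration_scale * (nu_ref / nu) — the
evanescent field penetrates deeper at longer wavelengths, and absorbance
scales approximately linearly with the number of reflections.

Measured intensities are synthesised as a smooth source envelope attenuated
by the absorbance, with per-point multiplicative detector noise, and — in the
ATR configuration — a multiplicative sinusoidal fringe (random phase and
period per sample) emulating etalon-like interference in the optical path.

Cohorts mirror the animal study design: a handful of individuals, each
contributing many samples; per-individual matrix composition (protein and
lactate levels, smooth spectral baseline) drawn once per individual; a subset
of samples spiked with concentrated glucose stock (adding < 5% volume) to
extend the physiological concentration range.

The module-level defaults below are the frozen study conditions used by the
benchmark scenarios; see docs/methods.md for how they were chosen.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .spectra import (
    SpectraSet,
    Spectrum,
    SpectraError,
    WavenumberGrid,
    compute_absorbance,
    default_grid,
)

__all__ = [
    "AbsorptionBand",
    "ComponentLibrary",
    "SampleComposition",
    "InstrumentModel",
    "CohortSpec",
    "SimulationError",
    "SpikeVolumeError",
    "default_library",
    "default_instrument",
    "component_absorptivity",
    "true_absorbance",
    "measured_intensities",
    "spike",
    "individual_effects",
    "generate_cohort",
    "MATRIX_LEVELS",
    "NOISE_SD",
]


class SimulationError(ValueError):
    """Raised for invalid simulation inputs or nonpositive intensities."""


class SpikeVolumeError(SimulationError):
    """Raised when a glucose spike would add >= 5% extra volume."""


# ---------------------------------------------------------------------------
# Frozen study conditions (generator defaults)
# ---------------------------------------------------------------------------

#: Matrix composition per fluid type, mg/dL.  Plasma total protein is 2.2x the
#: peritoneal level (measured plasma protein was more than twice as high).
MATRIX_LEVELS: Dict[str, Dict[str, float]] = {
    "peritoneal": {"protein": 3000.0, "lactate": 20.0},
    "plasma": {"protein": 6600.0, "lactate": 30.0},
}

#: Relative intensity noise (sd of the multiplicative detector noise) per
#: measurement mode.  Frozen calibration: chosen so the benchmark scenarios
#: land near the reference prediction errors; a calibration, not a measurement.
NOISE_SD: Dict[str, float] = {"transmission": 1.5e-4, "atr": 3.5e-5}

#: ATR fringe defaults: relative amplitude and the per-sample period range
#: (cm^-1).  Periods of 6-7.5 cm^-1 put the fringe at raw-DFT bins 37-46 on
#: the 276-point grid, beyond the Fourier filter's cutoff*multiplier = 36.4,
#: while analyte bands (width >= 15 cm^-1) stay below bin ~18.
FRINGE_AMPLITUDE_ATR = 0.01
FRINGE_PERIOD_RANGE = (6.0, 7.5)


@dataclass(frozen=True)
class AbsorptionBand:
    """One absorption band: centre and FWHM in cm^-1, peak absorptivity in
    AU per (mg/dL) per mm of pathlength."""

    center: float
    width: float
    peak_absorptivity: float
    shape: str = "gaussian"  # {"gaussian", "lorentzian"}

    def __post_init__(self):
        if self.width <= 0:
            raise SimulationError("band width must be positive")
        if self.peak_absorptivity < 0:
            raise SimulationError("peak absorptivity must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise SimulationError(f"unknown band shape {self.shape!r}")

    def profile(self, grid: WavenumberGrid) -> np.ndarray:
        """Absorptivity profile of this band on the grid."""
        nu = grid.values
        if self.shape == "gaussian":
            # FWHM parameterisation: value at center +- width/2 is peak/2
            return self.peak_absorptivity * np.exp(
                -4.0 * np.log(2.0) * ((nu - self.center) / self.width) ** 2
            )
        hw = self.width / 2.0
        return self.peak_absorptivity * hw**2 / ((nu - self.center) ** 2 + hw**2)


@dataclass(frozen=True)
class ComponentLibrary:
    """Absorption bands per analyte.  The glucose entry must include the
    1035 cm^-1 band — the fingerprint feature the calibration relies on."""

    components: Dict[str, Tuple[AbsorptionBand, ...]]

    def __post_init__(self):
        comps = {k: tuple(v) for k, v in self.components.items()}
        object.__setattr__(self, "components", comps)
        for name, bands in comps.items():
            if len(bands) == 0 and name != "_empty":
                raise SimulationError(f"analyte {name!r} has no bands")
        if "glucose" in comps:
            centers = [b.center for b in comps["glucose"]]
            if not any(abs(c - 1035.0) < 1.0 for c in centers):
                raise SimulationError("glucose entry must include a 1035 cm^-1 band")


def default_library() -> ComponentLibrary:
    """Band library emulating the qualitative shape of biofluid mid-IR spectra.

    Glucose: fingerprint bands at 1035, 1080 and 1110 cm^-1.  Protein
    (albumin-like): one broad band near 1080 cm^-1; the slowly varying part of
    the protein background is carried by the per-individual baseline.
    Lactate: minor band near 1125 cm^-1.  Band parameters are tunable
    generator defaults, not literature constants.
    """
    return ComponentLibrary(
        {
            "glucose": (
                AbsorptionBand(1035.0, 16.0, 2.5e-5),
                AbsorptionBand(1080.0, 20.0, 1.5e-5),
                AbsorptionBand(1110.0, 24.0, 1.0e-5),
            ),
            "protein": (AbsorptionBand(1080.0, 70.0, 1.2e-5),),
            "lactate": (AbsorptionBand(1125.0, 20.0, 2.0e-5),),
        }
    )


@dataclass(frozen=True)
class SampleComposition:
    """What is in one sample: glucose, matrix analytes, and the smooth
    per-individual spectral baseline (offset/slope/curvature in AU)."""

    glucose: float  # mg/dL
    matrix_concs: Dict[str, float]  # analyte -> mg/dL
    individual_id: str = ""
    dilution_factor: float = 1.0  # in (0.95, 1]; < 1 after spiking
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    baseline_curve: float = 0.0

    def __post_init__(self):
        if self.glucose < 0 or any(c < 0 for c in self.matrix_concs.values()):
            raise SimulationError("concentrations must be >= 0")
        if not (0.95 < self.dilution_factor <= 1.0):
            raise SimulationError(
                "dilution_factor must lie in (0.95, 1] (< 5% added volume)"
            )


@dataclass(frozen=True)
class InstrumentModel:
    """Measurement configuration for one of the two optical setups.

    Transmission: fixed pathlength (um).  ATR: ``n_reflections`` on the
    internal reflection element, each contributing an effective pathlength
    ``penetration_scale_um * (ref_wavenumber / nu)`` um.
    """

    mode: str  # {"transmission", "atr"}
    grid: WavenumberGrid = field(default_factory=default_grid)
    pathlength_um: float = 200.0
    n_reflections: int = 11
    penetration_scale_um: float = 3.0
    ref_wavenumber: float = 1035.0
    fringe_amplitude: float = 0.0
    fringe_period_range: Tuple[float, float] = FRINGE_PERIOD_RANGE
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.mode not in ("transmission", "atr"):
            raise SimulationError(f"unknown mode {self.mode!r}")
        if self.pathlength_um <= 0 or self.penetration_scale_um <= 0:
            raise SimulationError("pathlengths must be positive")
        if self.n_reflections < 1:
            raise SimulationError("n_reflections must be >= 1")
        if self.fringe_amplitude < 0 or self.noise_sd < 0:
            raise SimulationError("fringe_amplitude and noise_sd must be >= 0")

    def pathlength_mm(self) -> np.ndarray:
        """Effective pathlength in mm at every grid wavenumber."""
        if self.mode == "transmission":
            return np.full(len(self.grid), self.pathlength_um / 1000.0)
        d_e = self.penetration_scale_um * (self.ref_wavenumber / self.grid.values)
        return self.n_reflections * d_e / 1000.0


def default_instrument(mode: str, noise: bool = True) -> InstrumentModel:
    """The frozen benchmark instrument for a mode, with or without noise."""
    if mode == "transmission":
        return InstrumentModel(
            mode="transmission",
            noise_sd=NOISE_SD["transmission"] if noise else 0.0,
        )
    if mode == "atr":
        return InstrumentModel(
            mode="atr",
            fringe_amplitude=FRINGE_AMPLITUDE_ATR if noise else 0.0,
            noise_sd=NOISE_SD["atr"] if noise else 0.0,
        )
    raise SimulationError(f"unknown mode {mode!r}")


def component_absorptivity(
    library: ComponentLibrary, analyte: str, grid: WavenumberGrid
) -> np.ndarray:
    """Absorptivity profile of one analyte: the superposition of its bands,
    in AU per (mg/dL) per mm."""
    if analyte not in library.components:
        raise KeyError(
            f"analyte {analyte!r} not in library "
            f"(have: {sorted(library.components)})"
        )
    out = np.zeros(len(grid))
    for band in library.components[analyte]:
        out += band.profile(grid)
    return out


def _baseline(comp: SampleComposition, grid: WavenumberGrid) -> np.ndarray:
    """Smooth per-individual baseline: offset + slope + gentle curvature on a
    normalised coordinate u in [-1, 1] across the grid."""
    nu = grid.values
    u = 2.0 * (nu - nu.min()) / (nu.max() - nu.min()) - 1.0
    return (
        comp.baseline_offset
        + comp.baseline_slope * u
        + comp.baseline_curve * (u**2 - 1.0 / 3.0)
    )


def true_absorbance(
    composition: SampleComposition,
    library: ComponentLibrary,
    instrument: InstrumentModel,
) -> Spectrum:
    """Noiseless absorbance of a sample under an instrument model."""
    grid = instrument.grid
    path_mm = instrument.pathlength_mm()
    a = np.zeros(len(grid))
    concs = dict(composition.matrix_concs)
    concs["glucose"] = concs.get("glucose", 0.0) + composition.glucose
    for analyte, conc in concs.items():
        if conc == 0.0:
            continue
        a += component_absorptivity(library, analyte, grid) * conc * path_mm
    a += _baseline(composition, grid)
    return Spectrum(
        grid=grid,
        values=a,
        kind="absorbance",
        individual_id=composition.individual_id,
        mode=instrument.mode,
        reference_glucose=composition.glucose,
    )


def _source_envelope(grid: WavenumberGrid) -> np.ndarray:
    """Smooth positive laser power envelope across the tuning range."""
    nu = grid.values
    return 1.0 + 0.4 * np.exp(-(((nu - 1060.0) / 180.0) ** 2))


def measured_intensities(
    noiseless: Spectrum, instrument: InstrumentModel, rng_seed: int
) -> Tuple[Spectrum, Spectrum]:
    """Simulate the paired (sample I, reference I0) intensity measurement.

    ``I0`` is the source envelope with multiplicative detector noise; ``I``
    is the envelope attenuated by ``10**(-A)``, carrying the sinusoidal
    fringe term (random phase and period per sample) and its own detector
    noise.  Identical seeds give bit-identical output.
    """
    if noiseless.kind != "absorbance":
        raise SimulationError("measured_intensities expects an absorbance spectrum")
    grid = noiseless.grid
    nu = grid.values
    rng = np.random.default_rng(rng_seed)
    # Draw order is part of the determinism contract: phase, period, then the
    # two noise vectors.  Scaling noise_sd with a fixed seed rescales the same
    # noise realisation.
    phase = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = instrument.fringe_period_range
    period = rng.uniform(lo, hi)
    eps_ref = rng.standard_normal(len(grid))
    eps_sam = rng.standard_normal(len(grid))

    envelope = _source_envelope(grid)
    fringe = instrument.fringe_amplitude * np.sin(2.0 * np.pi * nu / period + phase)
    i0 = envelope * (1.0 + instrument.noise_sd * eps_ref)
    i = (
        envelope
        * (1.0 + fringe)
        * np.power(10.0, -noiseless.values)
        * (1.0 + instrument.noise_sd * eps_sam)
    )
    if np.any(i0 <= 0) or np.any(i <= 0):
        raise SimulationError(
            "simulated intensity is nonpositive; lower noise_sd or "
            "fringe_amplitude (values are never clipped)"
        )
    mk = lambda v: Spectrum(
        grid=grid,
        values=v,
        kind="intensity",
        sample_id=noiseless.sample_id,
        individual_id=noiseless.individual_id,
        mode=instrument.mode,
        reference_glucose=noiseless.reference_glucose,
    )
    return mk(i), mk(i0)


def spike(
    composition: SampleComposition,
    target_glucose: float,
    stock_conc: float = 10000.0,
    volume_ml: float = 1.0,
) -> SampleComposition:
    """Spike a sample with concentrated glucose stock to a target level.

    The added volume ``v = V * (c_t - c_0) / (c_s - c_t)`` dilutes the matrix
    by ``V / (V + v)``; spikes that would add >= 5% volume are rejected, as
    in the wet-lab protocol the generator emulates.
    """
    c0 = composition.glucose
    if target_glucose == c0:
        return composition
    if not (stock_conc > target_glucose > c0):
        raise SimulationError(
            "spike requires stock_conc > target_glucose > current glucose; "
            f"got stock={stock_conc}, target={target_glucose}, current={c0}"
        )
    v = volume_ml * (target_glucose - c0) / (stock_conc - target_glucose)
    if v / volume_ml >= 0.05:
        raise SpikeVolumeError(
            f"spike to {target_glucose} mg/dL needs {100 * v / volume_ml:.1f}% "
            "added volume (>= 5%); use a more concentrated stock"
        )
    f = volume_ml / (volume_ml + v)
    return replace(
        composition,
        glucose=target_glucose,
        matrix_concs={k: c * f for k, c in composition.matrix_concs.items()},
        dilution_factor=composition.dilution_factor * f,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated cohort.

    The variability knobs describe what differs between and within
    individuals: ``matrix_cv`` is the per-individual coefficient of variation
    of matrix analyte levels, ``within_cv`` the sample-to-sample jitter, and
    the ``baseline_*_sd`` terms the spread of the per-individual smooth
    baseline (AU).  Setting them to zero yields exactly
    glucose/protein/lactate three-component spectra.
    """

    n_individuals: int
    samples_per_individual: int
    base_glucose_range: Tuple[float, float]
    spike_fraction: float = 0.0
    spike_target_range: Tuple[float, float] = (150.0, 426.0)
    matrix_level: str = "peritoneal"  # {"peritoneal", "plasma"}
    seed: int = 0
    n_samples: Optional[int] = None  # keep only the first n_samples
    matrix_cv: float = 0.06
    within_cv: float = 0.03
    baseline_offset_sd: float = 5.0e-5
    baseline_slope_sd: float = 5.0e-5
    baseline_curve_sd: float = 2.5e-5
    reference_error_sd: float = 0.0  # mg/dL; 0 = exact ground truth

    def __post_init__(self):
        if self.n_individuals < 1 or self.samples_per_individual < 1:
            raise SimulationError("cohort must have >= 1 individual and sample")
        for lo, hi in (self.base_glucose_range, self.spike_target_range):
            if not lo < hi:
                raise SimulationError("ranges must satisfy lo < hi")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise SimulationError("spike_fraction must be in [0, 1]")
        if self.matrix_level not in MATRIX_LEVELS:
            raise SimulationError(f"unknown matrix_level {self.matrix_level!r}")


def _id_seed(individual_id: str) -> int:
    """Stable 31-bit seed derived from an individual ID string."""
    return zlib.crc32(individual_id.encode("utf-8")) & 0x7FFFFFFF


def individual_effects(
    individual_id: str, spec: CohortSpec, baseline_scale: float = 1.0
) -> dict:
    """Per-individual matrix parameters, a pure function of the ID string.

    Returns multiplicative matrix-level factors and the baseline
    offset/slope/curvature drawn from an RNG seeded by the ID, so any two
    samples of the same individual share the same matrix background.
    ``baseline_scale`` rescales the baseline spread with the instrument's
    effective pathlength: matrix background absorbance, like any absorbance,
    grows with the optical path through the sample.
    """
    rng = np.random.default_rng(_id_seed(individual_id))
    base = MATRIX_LEVELS[spec.matrix_level]
    factors = {
        name: max(0.0, 1.0 + spec.matrix_cv * rng.standard_normal())
        for name in sorted(base)
    }
    return {
        "matrix_concs": {name: base[name] * factors[name] for name in sorted(base)},
        "baseline_offset": baseline_scale * spec.baseline_offset_sd * rng.standard_normal(),
        "baseline_slope": baseline_scale * spec.baseline_slope_sd * rng.standard_normal(),
        "baseline_curve": baseline_scale * spec.baseline_curve_sd * rng.standard_normal(),
    }


def generate_cohort(
    spec: CohortSpec,
    library: Optional[ComponentLibrary] = None,
    instrument: Optional[InstrumentModel] = None,
) -> SpectraSet:
    """Simulate a full cohort as a SpectraSet (absorbance + metadata).

    Individual IDs embed the cohort seed ("pig3-s17") so the deterministic
    per-individual effects differ between seeds.  The recorded reference
    glucose is exact ground truth unless ``reference_error_sd > 0``.
    """
    library = default_library() if library is None else library
    instrument = (
        default_instrument("transmission") if instrument is None else instrument
    )
    rng = np.random.default_rng(spec.seed)
    rows: List[np.ndarray] = []
    glucose: List[float] = []
    groups: List[str] = []
    sample_ids: List[str] = []
    lo, hi = spec.base_glucose_range
    s_lo, s_hi = spec.spike_target_range
    # Baseline spread is specified at the 200 um transmission reference path
    # and scales with the instrument's mean effective pathlength.
    baseline_scale = float(np.mean(instrument.pathlength_mm())) / 0.2
    for i in range(spec.n_individuals):
        ind_id = f"pig{i + 1}-s{spec.seed}"
        eff = individual_effects(ind_id, spec, baseline_scale)
        for j in range(spec.samples_per_individual):
            g0 = rng.uniform(lo, hi)
            jitter = {
                name: conc * max(0.0, 1.0 + spec.within_cv * rng.standard_normal())
                for name, conc in eff["matrix_concs"].items()
            }
            comp = SampleComposition(
                glucose=g0,
                matrix_concs=jitter,
                individual_id=ind_id,
                baseline_offset=eff["baseline_offset"],
                baseline_slope=eff["baseline_slope"],
                baseline_curve=eff["baseline_curve"],
            )
            do_spike = rng.uniform() < spec.spike_fraction
            target = rng.uniform(s_lo, s_hi)  # drawn either way: stable stream
            if do_spike and target > g0:
                comp = spike(comp, target)
            noiseless = true_absorbance(comp, library, instrument)
            sample_seed = int(rng.integers(0, 2**31 - 1))
            i_sam, i_ref = measured_intensities(noiseless, instrument, sample_seed)
            ab = compute_absorbance(i_sam, i_ref)
            ref_g = comp.glucose
            if spec.reference_error_sd > 0:
                ref_g += spec.reference_error_sd * rng.standard_normal()
            rows.append(ab.values)
            glucose.append(ref_g)
            groups.append(ind_id)
            sample_ids.append(f"{ind_id}-{j:02d}")
    sset = SpectraSet(
        grid=instrument.grid,
        matrix=np.vstack(rows),
        glucose=np.array(glucose),
        groups=np.array(groups, dtype=object),
        mode=instrument.mode,
        sample_ids=np.array(sample_ids, dtype=object),
    )
    if spec.n_samples is not None:
        sset = sset.subset(np.arange(spec.n_samples))
    return sset
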