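import numpy as np
import pytest

from mirglucose.simulate import (
    AbsorptionBand,
    CohortSpec,
    ComponentLibrary,
    InstrumentModel,
    SampleComposition,
    SimulationError,
    SpikeVolumeError,
    component_absorptivity,
    default_instrument,
    default_library,
    generate_cohort,
    measured_intensities,
    spike,
    true_absorbance,
)
from mirglucose.spectra import compute_absorbance, default_grid

from conftest import make_noiseless_cohort


@pytest.fixture
def library():
    return default_library()


class TestComponentAbsorptivity:
    def test_empty_band_list_gives_zero_profile(self, grid):
        lib = ComponentLibrary({"glucose": (AbsorptionBand(1035.0, 10.0, 1e-5),),
                                "_empty": ()})
        np.testing.assert_array_equal(
            component_absorptivity(lib, "_empty", grid), 0.0
        )

    @pytest.mark.parametrize("shape", ["gaussian", "lorentzian"])
    def test_peak_value_at_band_center(self, grid, shape):
        band = AbsorptionBand(1100.0, 20.0, 3e-5, shape=shape)
        lib = ComponentLibrary({"glucose": (AbsorptionBand(1035.0, 10.0, 1e-5),),
                                "x": (band,)})
        prof = component_absorptivity(lib, "x", grid)
        center = np.argmin(np.abs(grid.values - 1100.0))
        assert prof[center] == pytest.approx(3e-5, rel=1e-12)
        # half maximum at center +- width/2 (FWHM definition)
        half = np.argmin(np.abs(grid.values - 1110.0))
        assert prof[half] == pytest.approx(1.5e-5, rel=1e-9)

    def test_superposition_of_identical_bands(self, grid):
        b = AbsorptionBand(1050.0, 15.0, 2e-5)
        one = ComponentLibrary({"glucose": (AbsorptionBand(1035.0, 10.0, 1e-5),),
                                "x": (b,)})
        two = ComponentLibrary({"glucose": (AbsorptionBand(1035.0, 10.0, 1e-5),),
                                "x": (b, b)})
        np.testing.assert_allclose(
            component_absorptivity(two, "x", grid),
            2.0 * component_absorptivity(one, "x", grid),
            rtol=1e-14,
        )

    def test_unknown_analyte_is_a_lookup_error(self, grid, library):
        with pytest.raises(KeyError, match="caffeine"):
            component_absorptivity(library, "caffeine", grid)

    def test_glucose_entry_must_have_fingerprint_band(self):
        with pytest.raises(SimulationError, match="1035"):
            ComponentLibrary({"glucose": (AbsorptionBand(1100.0, 10.0, 1e-5),)})


class TestTrueAbsorbance:
    def test_empty_sample_gives_zero_spectrum(self, library):
        comp = SampleComposition(glucose=0.0, matrix_concs={})
        a = true_absorbance(comp, library, default_instrument("transmission", noise=False))
        np.testing.assert_array_equal(a.values, 0.0)

    def test_atr_absorbance_linear_in_reflection_count(self, library):
        comp = SampleComposition(glucose=200.0, matrix_concs={"protein": 3000.0})
        atr1 = InstrumentModel(mode="atr", n_reflections=11)
        atr2 = InstrumentModel(mode="atr", n_reflections=22)
        a1 = true_absorbance(comp, library, atr1).values
        a2 = true_absorbance(comp, library, atr2).values
        np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-12)

    def test_transmission_absorbance_linear_in_pathlength(self, library):
        comp = SampleComposition(glucose=100.0, matrix_concs={"lactate": 20.0})
        a200 = true_absorbance(
            comp, library, InstrumentModel(mode="transmission", pathlength_um=200.0)
        ).values
        a400 = true_absorbance(
            comp, library, InstrumentModel(mode="transmission", pathlength_um=400.0)
        ).values
        np.testing.assert_allclose(a400, 2.0 * a200, rtol=1e-12)

    def test_superposition_in_concentrations(self, library):
        inst = default_instrument("transmission", noise=False)
        g = true_absorbance(
            SampleComposition(glucose=150.0, matrix_concs={}), library, inst
        ).values
        m = true_absorbance(
            SampleComposition(glucose=0.0, matrix_concs={"protein": 2500.0}),
            library, inst,
        ).values
        both = true_absorbance(
            SampleComposition(glucose=150.0, matrix_concs={"protein": 2500.0}),
            library, inst,
        ).values
        np.testing.assert_allclose(both, g + m, rtol=1e-12)

    def test_atr_effective_path_grows_with_wavelength(self, library):
        # lower wavenumber = longer wavelength = deeper evanescent field
        inst = InstrumentModel(mode="atr")
        path = inst.pathlength_mm()
        assert path[-1] > path[0]  # grid is descending in wavenumber
        assert path[np.argmin(np.abs(inst.grid.values - 1035.0))] == pytest.approx(
            11 * 3.0 / 1000.0, rel=1e-12
        )


class TestMeasuredIntensities:
    def test_zero_noise_round_trips_through_absorbance(self, library):
        comp = SampleComposition(glucose=300.0, matrix_concs={"protein": 3000.0})
        inst = default_instrument("transmission", noise=False)
        noiseless = true_absorbance(comp, library, inst)
        i, i0 = measured_intensities(noiseless, inst, rng_seed=4)
        back = compute_absorbance(i, i0)
        np.testing.assert_allclose(back.values, noiseless.values, rtol=1e-10,
                                   atol=1e-14)

    def test_same_seed_is_bit_identical(self, library):
        comp = SampleComposition(glucose=120.0, matrix_concs={"protein": 3000.0})
        inst = default_instrument("atr")
        noiseless = true_absorbance(comp, library, inst)
        a = measured_intensities(noiseless, inst, rng_seed=9)
        b = measured_intensities(noiseless, inst, rng_seed=9)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)
        c = measured_intensities(noiseless, inst, rng_seed=10)
        assert not np.array_equal(a[0].values, c[0].values)

    def test_fringe_small_signal_expansion(self, grid):
        """With A = 0 and a 1% fringe, the measured absorbance is a sinusoid
        of relative amplitude ~= 0.01 / ln(10), matching the closed-form
        small-signal expansion -log10(1 + a sin) ~= -(a / ln 10) sin."""
        amp = 0.01
        inst = InstrumentModel(mode="atr", fringe_amplitude=amp, noise_sd=0.0)
        flat = true_absorbance(
            SampleComposition(glucose=0.0, matrix_concs={}),
            default_library(), inst,
        )
        i, i0 = measured_intensities(flat, inst, rng_seed=21)
        a_meas = compute_absorbance(i, i0).values
        # direct evaluation: replay the generator's documented draw order
        rng = np.random.default_rng(21)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        period = rng.uniform(*inst.fringe_period_range)
        fringe = amp * np.sin(2.0 * np.pi * inst.grid.values / period + phase)
        np.testing.assert_allclose(a_meas, -np.log10(1.0 + fringe), rtol=1e-12)
        # small-signal amplitude
        assert np.max(np.abs(a_meas)) == pytest.approx(amp / np.log(10), rel=0.02)

    def test_excessive_noise_raises_instead_of_clipping(self, library):
        comp = SampleComposition(glucose=0.0, matrix_concs={})
        inst = InstrumentModel(mode="transmission", noise_sd=2.0)
        flat = true_absorbance(comp, library, inst)
        with pytest.raises(SimulationError, match="nonpositive"):
            measured_intensities(flat, inst, rng_seed=0)


class TestSpike:
    def test_added_volume_matches_algebraic_oracle(self):
        comp = SampleComposition(glucose=140.0, matrix_concs={"protein": 3000.0})
        out = spike(comp, 426.0, stock_conc=10000.0, volume_ml=1.0)
        v = 1.0 * (426.0 - 140.0) / (10000.0 - 426.0)
        assert v == pytest.approx(0.0299, abs=5e-4)  # ~2.99% added volume
        # conservation of mass: (c0 V + cs v) / (V + v) = c_target
        assert (140.0 * 1.0 + 10000.0 * v) / (1.0 + v) == pytest.approx(426.0)
        assert out.glucose == 426.0
        assert out.dilution_factor == pytest.approx(1.0 / (1.0 + v), rel=1e-12)
        assert out.matrix_concs["protein"] == pytest.approx(3000.0 / (1.0 + v))

    def test_spike_to_current_level_is_identity(self):
        comp = SampleComposition(glucose=90.0, matrix_concs={"lactate": 20.0})
        assert spike(comp, 90.0) is comp

    def test_five_percent_volume_limit_enforced(self):
        comp = SampleComposition(glucose=33.0, matrix_concs={})
        with pytest.raises(SpikeVolumeError, match="5%"):
            spike(comp, 426.0, stock_conc=5000.0)

    def test_full_study_range_achievable_with_default_stock(self):
        # the hardest spike in the design: 33 -> 426 mg/dL
        out = spike(SampleComposition(glucose=33.0, matrix_concs={}), 426.0)
        assert out.glucose == 426.0
        assert out.dilution_factor > 0.95

    def test_invalid_targets_rejected(self):
        comp = SampleComposition(glucose=100.0, matrix_concs={})
        with pytest.raises(SimulationError):
            spike(comp, 50.0)  # below current
        with pytest.raises(SimulationError):
            spike(comp, 400.0, stock_conc=300.0)  # stock below target


class TestGenerateCohort:
    def test_study_sized_cohort_structure(self):
        spec = CohortSpec(
            n_individuals=5, samples_per_individual=16,
            base_glucose_range=(33.0, 140.0), spike_fraction=0.5, seed=1,
        )
        sset = generate_cohort(spec)
        assert sset.n_samples == 80
        assert len(sset.individuals()) == 5
        counts = {g: np.sum(sset.groups == g) for g in sset.individuals()}
        assert all(c == 16 for c in counts.values())

    def test_unspiked_cohort_stays_in_base_range(self):
        spec = CohortSpec(
            n_individuals=3, samples_per_individual=12,
            base_glucose_range=(33.0, 140.0), spike_fraction=0.0, seed=2,
        )
        sset = generate_cohort(spec)
        assert np.all(sset.glucose >= 33.0) and np.all(sset.glucose <= 140.0)

    def test_glucose_always_within_design_envelope(self):
        spec = CohortSpec(
            n_individuals=4, samples_per_individual=20,
            base_glucose_range=(33.0, 140.0), spike_fraction=0.7,
            spike_target_range=(150.0, 426.0), seed=3,
        )
        sset = generate_cohort(spec)
        assert np.all(sset.glucose >= 33.0) and np.all(sset.glucose <= 426.0)
        assert sset.glucose.max() > 140.0  # spiking actually happened

    def test_same_spec_and_seed_bit_identical(self):
        spec = CohortSpec(
            n_individuals=3, samples_per_individual=8,
            base_glucose_range=(33.0, 140.0), spike_fraction=0.5, seed=7,
        )
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        np.testing.assert_array_equal(a.glucose, b.glucose)
        assert list(a.groups) == list(b.groups)

    def test_plasma_matrix_doubles_total_absorbance(self):
        peri = make_noiseless_cohort(seed=5, matrix_level="peritoneal",
                                     n_individuals=3, samples_per_individual=4)
        plas = make_noiseless_cohort(seed=5, matrix_level="plasma",
                                     n_individuals=3, samples_per_individual=4)
        assert plas.matrix.mean() > 1.8 * peri.matrix.mean()

    def test_sample_cap_keeps_first_n(self):
        spec = CohortSpec(
            n_individuals=2, samples_per_individual=11,
            base_glucose_range=(65.0, 105.0), seed=4, n_samples=21,
        )
        sset = generate_cohort(spec)
        assert sset.n_samples == 21
        assert len(sset.individuals()) == 2
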