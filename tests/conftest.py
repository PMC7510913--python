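import numpy as np
import pytest

from mirglucose.simulate import (
    CohortSpec,
    default_instrument,
    generate_cohort,
)
from mirglucose.spectra import SpectraSet, WavenumberGrid, default_grid


@pytest.fixture
def grid():
    return default_grid()


def make_noiseless_cohort(seed=0, mode="transmission", n_individuals=5,
                          samples_per_individual=10, matrix_level="peritoneal"):
    """Noiseless 3-component cohort: glucose, protein and lactate vary, no
    baseline, no detector noise, no fringe — spectra are exact linear
    mixtures of three absorptivity profiles."""
    spec = CohortSpec(
        n_individuals=n_individuals,
        samples_per_individual=samples_per_individual,
        base_glucose_range=(33.0, 140.0),
        spike_fraction=0.5,
        spike_target_range=(150.0, 426.0),
        matrix_level=matrix_level,
        seed=seed,
        baseline_offset_sd=0.0,
        baseline_slope_sd=0.0,
        baseline_curve_sd=0.0,
    )
    return generate_cohort(spec, instrument=default_instrument(mode, noise=False))


@pytest.fixture
def noiseless_cohort():
    return make_noiseless_cohort()


@pytest.fixture
def noisy_cohort():
    spec = CohortSpec(
        n_individuals=4,
        samples_per_individual=10,
        base_glucose_range=(33.0, 140.0),
        spike_fraction=0.5,
        spike_target_range=(150.0, 426.0),
        seed=11,
    )
    return generate_cohort(spec, instrument=default_instrument("transmission"))


def random_set(seed=0, n=24, p=40, n_groups=4):
    """A small random SpectraSet (no physical structure) for API tests."""
    rng = np.random.default_rng(seed)
    g = WavenumberGrid(np.linspace(1200.0, 1000.0, p))
    return SpectraSet(
        grid=g,
        matrix=rng.normal(size=(n, p)),
        glucose=rng.uniform(50.0, 400.0, size=n),
        groups=np.array([f"g{i % n_groups}" for i in range(n)], dtype=object),
        mode="transmission",
    )


@pytest.fixture
def small_set():
    return random_set()
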