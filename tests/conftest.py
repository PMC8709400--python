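import numpy as np
import pytest

from petalvision.spectra import Spectrum, make_grid, resample
from petalvision.synthetic_data import (
    SimConfig,
    SpectrumModelParams,
    TreatmentEffects,
    simulate_dataset,
)


def make_spectrum(wavelengths, reflectance, **meta) -> Spectrum:
    return Spectrum(np.asarray(wavelengths, float), np.asarray(reflectance, float), meta)


def constant_spectrum(value=0.4, lo=325.0, hi=1075.0, step=1.0, **meta) -> Spectrum:
    grid = make_grid(lo, hi, step)
    return make_spectrum(grid, np.full(grid.size, value), **meta)


@pytest.fixture(scope="session")
def default_params() -> SpectrumModelParams:
    return SpectrumModelParams()


@pytest.fixture(scope="session")
def default_effects() -> TreatmentEffects:
    return TreatmentEffects()


@pytest.fixture(scope="session")
def small_dataset():
    """Field-design-sized synthetic dataset: 4 treatments x 2 plants x 9 petals."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def resampled_set(small_dataset):
    sset, _ = small_dataset
    grid = make_grid(325.0, 1075.0, 1.0)
    return sset.map(lambda sp: resample(sp, grid))
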