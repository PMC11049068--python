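import numpy as np
import pytest

from nirquant import SpectraSet, SyntheticConfig, generate
from nirquant.synthetic import ComponentSpec


def make_spectra(matrix, wavelengths=None, ids=None) -> SpectraSet:
    matrix = np.atleast_2d(np.asarray(matrix, float))
    p = matrix.shape[1]
    if wavelengths is None:
        wavelengths = np.linspace(1000.0, 2500.0, p)
    return SpectraSet(absorbance=matrix, wavelengths_nm=wavelengths,
                      sample_ids=tuple(ids) if ids else ())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_band_component():
    return ComponentSpec(name="probe", band_centers_nm=(1600.0,),
                         band_widths_nm=(30.0,), band_heights=(0.01,),
                         concentration_min=1.0, concentration_max=5.0)


@pytest.fixture(scope="session")
def noiseless_rank1(single_band_component):
    """One component, one band, zero nuisance: spectra = conc x pure."""
    cfg = SyntheticConfig(n_samples=12, n_channels=80,
                          components=(single_band_component,),
                          baseline_amplitude=0.0, scatter_slope_sd=0.0,
                          scatter_offset_sd=0.0, noise_sd=0.0, seed=42)
    return generate(cfg)


@pytest.fixture(scope="session")
def scatter_only_dataset():
    """Default components, nonzero scatter, zero baseline/noise."""
    cfg = SyntheticConfig(n_samples=20, n_channels=120,
                          baseline_amplitude=0.0, scatter_slope_sd=0.3,
                          scatter_offset_sd=0.05, noise_sd=0.0, seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Small instance of the full default generator (all nuisance terms on)."""
    return generate(SyntheticConfig(n_samples=60, n_channels=200, seed=3))
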