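import numpy as np
import pytest

from ramanresist.spectra_io import SpectraMatrix, WavenumberGrid
from ramanresist.synthetic import (Band, NoiseModel, PhenotypeProfile,
                                   melanoma_profile, immune_profile)


@pytest.fixture(scope="session")
def grid():
    return WavenumberGrid.regular(600, 1800, 1.0)


@pytest.fixture(scope="session")
def coarse_grid():
    return WavenumberGrid.regular(600, 1800, 2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_band_profile(center=1003.0, amplitude=1.0, cv=0.0, fwhm=12.0):
    band = Band(center=center, fwhm=fwhm)
    return PhenotypeProfile("single", (band,), (amplitude,), band_cv=cv)


@pytest.fixture(scope="session")
def small_two_phenotype(coarse_grid):
    """120 cells, two noiseless-ish separable phenotypes."""
    from ramanresist.synthetic import synth_spectrum

    noise = NoiseModel(additive_noise_sd=0.01, baseline_poly_degree=3,
                       baseline_coeff_sd=0.01, spike_rate=0.0,
                       cell_scale_cv=0.05)
    rng = np.random.default_rng(7)
    profiles = {"mel": melanoma_profile(cv=0.05),
                "imm": immune_profile(cv=0.05)}
    rows, labels = [], []
    for name, prof in profiles.items():
        for _ in range(60):
            rows.append(synth_spectrum(prof, None, noise, coarse_grid, rng))
            labels.append(name)
    ids = np.array([f"c{i}" for i in range(len(rows))], dtype=object)
    return (SpectraMatrix(ids, coarse_grid, np.vstack(rows)),
            np.array(labels, dtype=object))
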