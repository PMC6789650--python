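import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from specunmix import ReferenceSet, Spectrum, find_isosbestic, normalize_to_isosbestic
from specunmix.synthetic import default_grid, make_reference_spectrum, preset_pair

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def dt_models():
    """Thymidine-like nucleoside and thymine-like base models."""
    return preset_pair("dT-thymine")


@pytest.fixture(scope="session")
def dt_pure_spectra(dt_models, grid):
    """Noise-free pure-compound spectra of the default pair at pH 13."""
    nuc, base = dt_models
    return (
        make_reference_spectrum(nuc, 13.0, grid),
        make_reference_spectrum(base, 13.0, grid),
    )


@pytest.fixture(scope="session")
def dt_refs(dt_pure_spectra):
    """Noiseless normalized ReferenceSet for the default pair (iso 278 nm)."""
    nuc, base = dt_pure_spectra
    iso = find_isosbestic(nuc, base)
    return ReferenceSet(
        spectra=(
            normalize_to_isosbestic(nuc, iso),
            normalize_to_isosbestic(base, iso),
        ),
        isosbestic_nm=iso,
        window=(250.0, 350.0),
        compound_ids=("dT", "thymine"),
    )


def flat_spectrum(grid, value, **meta):
    return Spectrum(grid, np.full(grid.shape, float(value)), meta)


@pytest.fixture(scope="session")
def make_flat(grid):
    def _make(value, **meta):
        return flat_spectrum(grid, value, **meta)

    return _make
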