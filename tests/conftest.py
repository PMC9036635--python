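import pytest

from cdsom import (
    SOMConfig,
    WavelengthGrid,
    default_basis,
    make_rc_spectrum,
    make_reference_set,
    train_som,
)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def basis(grid):
    return default_basis(grid)


@pytest.fixture(scope="session")
def rc_spectrum(basis):
    return make_rc_spectrum(basis)


@pytest.fixture(scope="session")
def refset(basis):
    """Noiseless 40-entry synthetic reference set."""
    return make_reference_set(40, seed=1, noise_sd=0.0, basis=basis)


@pytest.fixture(scope="session")
def small_config():
    """A small map that trains in well under a second."""
    return SOMConfig(rows=10, cols=10, epochs=40, seed=7)


@pytest.fixture(scope="session")
def small_map(refset, small_config):
    return train_som(refset, small_config)


@pytest.fixture(scope="session")
def trained_map(refset):
    """Full-size 50x50 map on the noiseless reference set (shared:
    training takes a few seconds)."""
    return train_som(refset, SOMConfig(seed=2))


@pytest.fixture(scope="session")
def refset60(basis):
    """Larger noiseless reference set, the coverage a melting analysis
    needs (real CD reference collections hold ~70 proteins)."""
    return make_reference_set(60, seed=1, noise_sd=0.0, basis=basis)


@pytest.fixture(scope="session")
def melt_map(refset60):
    return train_som(refset60, SOMConfig(seed=2))
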