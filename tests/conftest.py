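import numpy as np
import pytest

from flymosaic.spectra import (
    DEFAULT_GRID,
    WavelengthGrid,
    d65_illuminant,
    nomogram_receptor_set,
)


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def illuminant(grid):
    return d65_illuminant(grid)


@pytest.fixture(scope="session")
def receptors(grid):
    return nomogram_receptor_set(grid=grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
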