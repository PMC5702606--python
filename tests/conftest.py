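import numpy as np
import pytest

from metnmr.exchange import SpectralAxis
from metnmr.synthetic import default_axes, default_residue_models


@pytest.fixture(scope="session")
def models():
    return default_residue_models()


@pytest.fixture(scope="session")
def axes():
    return default_axes()


@pytest.fixture()
def carbon_axis():
    """A fine 13C axis for 1D lineshape work."""
    return SpectralAxis("13C", 201.0, 4000.0, 4096, carrier=16.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
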