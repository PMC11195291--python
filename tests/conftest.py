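import numpy as np
import pytest

from logprf import FieldGrid, HRFParams, WarpSpec
from logprf.config import make_fixtures


@pytest.fixture(scope="session")
def warp5():
    """The standard warp: k=5, rmax=8, c = 8/ln(41)."""
    return WarpSpec(k=5.0, rmax=8.0)


@pytest.fixture(scope="session")
def grid64():
    return FieldGrid.square(64, fov_deg=16.0)


@pytest.fixture(scope="session")
def canonical_hrf():
    return HRFParams.canonical()


@pytest.fixture(scope="session")
def fixtures():
    """Mini stimulus pair + 20 noiseless synthetic units (seed 0)."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
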