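import numpy as np
import pytest

from endospec import colorimetry as cm
from endospec.synthetic import colorchecker_reference


@pytest.fixture(scope="session")
def grid():
    return cm.SpectralGrid.default()


@pytest.fixture(scope="session")
def cmf(grid):
    return cm.load_cmfs(grid)


@pytest.fixture(scope="session")
def d65(grid):
    return cm.load_d65(grid)


@pytest.fixture(scope="session")
def white(d65, cmf):
    return cm.white_point(d65, cmf)


@pytest.fixture(scope="session")
def checker(grid):
    return colorchecker_reference(grid)


@pytest.fixture(scope="session")
def checker_array(checker):
    return np.stack([p.values for p in checker])


@pytest.fixture(scope="session")
def round_trip():
    """Noiseless full-chain round trip over the 24 checker patches."""
    from endospec.evaluation import round_trip_report

    return round_trip_report()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
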