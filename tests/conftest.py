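import numpy as np
import pytest
from hypothesis import settings

from antgrad import OccupancyMatrix, table1_fixture

settings.register_profile("antgrad", deadline=None, derandomize=True)
settings.load_profile("antgrad")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sites():
    return table1_fixture()


@pytest.fixture
def checkerboard_2x3():
    """Two singleton species on three baits: the worked null-model
    example (observed C = 1, exhaustive null mean = 2/3)."""
    return OccupancyMatrix(["A", "B"], ["b1", "b2", "b3"], [[1, 0, 0], [0, 1, 0]])
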