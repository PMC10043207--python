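import numpy as np
import pytest

from afablate import tissue


@pytest.fixture(scope="session")
def geometry128():
    return tissue.make_disk_geometry(128, 1)


@pytest.fixture(scope="session")
def small_disk(geometry128):
    fld = tissue.sample_base_fibrosis(geometry128, correlation_length=4.0, seed=3)
    return tissue.threshold_fibrosis(fld, geometry128, 0.6)


@pytest.fixture(scope="session")
def sheet40():
    return tissue.make_sheet((40, 40))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
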