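import numpy as np
import pytest

from mzsim import Scan
from mzsim.fixtures import make_fixture_db, make_roi_pool


def make_scan(scan_id, ms_level, rt, mzs, intensities, duration=0.5):
    return Scan(
        scan_id=scan_id,
        ms_level=ms_level,
        rt=rt,
        duration=duration,
        mzs=np.asarray(mzs, dtype=float),
        intensities=np.asarray(intensities, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def session_db():
    """A moderate fixture feature database shared across tests."""
    return make_fixture_db(rng=np.random.default_rng(777), rt_range=(10.0, 60.0))


@pytest.fixture(scope="session")
def session_roi_pool():
    return make_roi_pool(60, np.random.default_rng(778))
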