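import numpy as np
import pytest

from eodmap import synthetic as syn
from eodmap.arena import default_arena
from eodmap.eod import instantaneous_eod_rate


@pytest.fixture(scope="session")
def arena():
    return default_arena()


@pytest.fixture(scope="session")
def trial(arena):
    """One 10-min synthetic trial (trajectory truth, EOD train, EOD rate on
    the video grid), shared across unit tests."""
    tt = syn.generate_trajectory(arena, 600.0, seed=101)
    eod = syn.generate_eod_train(tt, arena, seed=102)
    rate = instantaneous_eod_rate(eod, grid=tt.trajectory.times)
    return tt, eod, rate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
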