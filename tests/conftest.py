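import numpy as np
import pytest

from phm.synthetic import SensorConfig, generate_recording, pad_schedule
from phm.preprocessing import preprocess
from phm.fusion import fuse_streams, make_windows
from phm.patterns import recording_stats


@pytest.fixture(scope="session")
def pad_seed0():
    """One default 70-s four-activity recording pair with ground truth."""
    imu, phy, truth = generate_recording(pad_schedule(70.0), SensorConfig(), seed=0)
    return imu, phy, truth


@pytest.fixture(scope="session")
def processed_seed0(pad_seed0):
    imu, phy, truth = pad_seed0
    imu_c, phy_f, orient, cal = preprocess(imu, phy)
    return imu_c, phy_f, orient, cal, truth


@pytest.fixture(scope="session")
def windows_seed0(processed_seed0):
    imu_c, phy_f, _orient, _cal, truth = processed_seed0
    fus = fuse_streams(imu_c, phy_f)
    wins = make_windows(fus)
    stats = recording_stats(fus)
    return fus, wins, stats, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
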