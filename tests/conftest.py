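import numpy as np
import pytest
from hypothesis import settings

import flywalk as fw

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def templates():
    return fw.default_templates()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_labeled_dataset():
    """200 rendered trajectories under default (Table 1) study conditions."""
    cfg = fw.GeneratorConfig(mean_peaks=6)
    return cfg, fw.simulate_dataset(cfg, 200, 202)


def straight_walk(n=30, speed=0.9, frame_rate=30.0, theta=0.0, tid="walk"):
    """Constant-velocity trajectory along the body axis."""
    t = np.arange(n) / frame_rate
    th = np.radians(theta)
    return fw.RawTrajectory(
        id=tid,
        frame_rate=frame_rate,
        times=t,
        x=speed * t * np.cos(th),
        y=speed * t * np.sin(th),
        theta=np.full(n, theta),
    )
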