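import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pgme.entropy import EntropyConfig
from pgme.signal_prep import StepCycleSet
from pgme.synthetic import GaitSimParams, simulate_epoch


@pytest.fixture(scope="session")
def gait_epoch():
    """Default 30-s synthetic walking epoch with ground-truth boundaries."""
    return simulate_epoch(GaitSimParams(seed=11))


@pytest.fixture(scope="session")
def short_epoch():
    """10-s epoch for faster pipeline-level tests."""
    return simulate_epoch(GaitSimParams(seed=12, duration=10.0))


@pytest.fixture(scope="session")
def fast_entropy_cfg():
    """Reduced PGME configuration used throughout the suite: scales 1-3,
    coarse q grid, few projection directions, shorter AMI scan."""
    return EntropyConfig(
        scales=(1, 2, 3),
        q_grid=np.array([-1.0, -0.5, 0.0, 0.5, 1.0]),
        n_dirs=8,
        ami_max_lag=40,
    )


def cycles_from_bounds(bounds, fs=100.0):
    return StepCycleSet(boundaries=bounds, fs=fs)
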