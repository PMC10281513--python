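import numpy as np
import pytest
from hypothesis import settings

from flysearch.trajectory import Trajectory

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_traj(x, y, dt=0.04, t0=0.0, led=None):
    """Trajectory from coordinate lists at a fixed frame interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = t0 + dt * np.arange(len(x))
    return Trajectory(t, x, y, led)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
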