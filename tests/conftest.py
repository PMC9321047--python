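import numpy as np
import pytest

from foci.trajectory_io import Trajectory


def make_trajectory(positions, interval=10.0, extents=None, **kwargs) -> Trajectory:
    """Build a Trajectory from a position array, frames `interval` s apart."""
    positions = np.asarray(positions, dtype=float)
    defaults = {"focus_id": "f1", "cell_id": "c1"}
    defaults.update(kwargs)
    return Trajectory(
        times=np.arange(len(positions), dtype=float) * interval,
        positions=positions,
        extents=extents,
        **defaults,
    )


@pytest.fixture
def ballistic():
    """Constant-step (1, 0, 0) trajectory: the perfectly directed limit."""
    steps = np.arange(12, dtype=float)
    pos = np.column_stack([steps, np.zeros(12), np.zeros(12)])
    return make_trajectory(pos)


@pytest.fixture
def random_walk_positions():
    """Reproducible unconfined Gaussian-step positions, (101, 3)."""
    rng = np.random.default_rng(7)
    return np.cumsum(rng.normal(0.0, 0.2, size=(101, 3)), axis=0)
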