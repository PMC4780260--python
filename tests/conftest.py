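import numpy as np
import pytest

from mazephys.core import MazeGeometry, Trajectory
from mazephys.simulate import BehaviourModel, simulate_trajectory


@pytest.fixture(scope="session")
def epm_geometry() -> MazeGeometry:
    return MazeGeometry.standard_epm()


@pytest.fixture(scope="session")
def epm_trajectory() -> Trajectory:
    """One seeded 20-min plus-maze exploration at 30 Hz."""
    return simulate_trajectory(
        BehaviourModel.epm(), duration=1200.0, rate=30.0, rng=101
    )


def make_labelled_trajectory(labels, dt=1.0 / 30.0, duration=None):
    """Hand-built labelled trajectory with uniform sampling."""
    labels = np.asarray(labels, dtype=object)
    times = np.arange(labels.size) * dt
    if duration is None:
        duration = labels.size * dt
    return Trajectory(
        sample_times=times, session_duration=duration, labels=labels
    )
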