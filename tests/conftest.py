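import numpy as np
import pytest

from fishtrack3d import (ContainerGeometry, OpticalModel, SimulationConfig,
                         Trajectory3D, simulate_pair_recording)


@pytest.fixture(scope="session")
def geometry():
    return ContainerGeometry()


@pytest.fixture(scope="session")
def optical_model(geometry):
    return OpticalModel.default(geometry)


@pytest.fixture(scope="session")
def control_trajectory(geometry):
    """One 60 s control fish, fixed seed, reused across read-only tests."""
    rec = simulate_pair_recording(
        SimulationConfig(duration_s=60.0), geometry, pair_seed=20240, )
    return rec.fish_a


def make_trajectory(times, positions, fish_id="fish"):
    return Trajectory3D(fish_id=fish_id, times_s=np.asarray(times, float),
                        positions_mm=np.asarray(positions, float))


def straight_line_trajectory(n=100, dt=0.025, start=(50.0, 50.0, 50.0),
                             velocity=(20.0, 0.0, 0.0)):
    t = np.arange(n) * dt
    pos = np.asarray(start) + t[:, None] * np.asarray(velocity)
    return make_trajectory(t, pos)
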