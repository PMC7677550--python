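import numpy as np
import pytest

from vrstress.core import TrajectorySeries
from vrstress.geometry import SceneGeometry
from vrstress.synth import TraitProfile, generate_cohort


@pytest.fixture(scope="session")
def geometry() -> SceneGeometry:
    return SceneGeometry()


@pytest.fixture(scope="session")
def profile() -> TraitProfile:
    return TraitProfile(
        vulnerability=0.0,
        thigmotaxis_bias=0.5,
        center_avoidance=0.5,
        gait_speed_cv=0.2,
        mean_nn=800.0,
        nn_sd=40.0,
        rsa_amplitude=20.0,
        resp_rate=15.0,
        scan_rate=6.0,
        walk_speed=0.6,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Four fully simulated subjects, reused across tests."""
    return generate_cohort(4, coupling=1.0, seed=11)


def make_trajectory(t, x, y, z=None, yaw=None) -> TrajectorySeries:
    t = np.asarray(t, dtype=float)
    x = np.broadcast_to(np.asarray(x, dtype=float), t.shape).copy()
    y = np.broadcast_to(np.asarray(y, dtype=float), t.shape).copy()
    z = (
        np.broadcast_to(np.asarray(z, dtype=float), t.shape).copy()
        if z is not None
        else np.full_like(t, 1.7)
    )
    yaw = (
        np.broadcast_to(np.asarray(yaw, dtype=float), t.shape).copy()
        if yaw is not None
        else np.zeros_like(t)
    )
    return TrajectorySeries(t=t, x=x, y=y, z=z, yaw=yaw)


@pytest.fixture(scope="session")
def stationary_traj() -> TrajectorySeries:
    t = np.arange(0, 30, 1 / 90)
    return make_trajectory(t, 1.0, 1.0)
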