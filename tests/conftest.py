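import numpy as np
import pytest

from gaitkit import GaitSpec, NoiseSpec, TrajectorySet, simulate_gait


@pytest.fixture(scope="session")
def clean_lateral():
    """Noiseless lateral treadmill bout with ground truth (shared, read-only)."""
    spec = GaitSpec(bout_duration_s=15.0)
    return simulate_gait(spec, NoiseSpec.noiseless(), view="lateral", seed=11)


@pytest.fixture(scope="session")
def clean_frontal():
    spec = GaitSpec(bout_duration_s=15.0)
    return simulate_gait(spec, NoiseSpec.noiseless(), view="near_frontal", seed=11)


def make_traj(positions, frame_rate=30.0, view="lateral", visibility=None, **kw):
    """Small hand-built trajectory from {landmark: (n, d) array} data."""
    positions = {k: np.asarray(v, float) for k, v in positions.items()}
    n = next(iter(positions.values())).shape[0]
    return TrajectorySet(
        frames=np.arange(n),
        positions=positions,
        visibility=visibility or {},
        frame_rate=frame_rate,
        view=view,
        **kw,
    )
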