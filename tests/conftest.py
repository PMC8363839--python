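import numpy as np
import pytest

from bilayerlab import ParticleTrajectory


def make_traj(positions, box=(13.0, 13.0, 10.0), dt=1.0, tags=None):
    """Assemble a ParticleTrajectory from an (F, N, 3) position array."""
    positions = np.asarray(positions, dtype=float)
    f, n, _ = positions.shape
    if tags is None:
        tags = np.array(["POPC-P"] * n, dtype=object)
    return ParticleTrajectory(
        positions=positions,
        boxes=np.tile(np.asarray(box, dtype=float), (f, 1)),
        times=np.arange(f) * dt,
        tags=np.asarray(tags, dtype=object),
        source="test",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
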