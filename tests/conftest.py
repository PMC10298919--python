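import numpy as np
import pytest
from hypothesis import settings

import ionmdmc as m
from ionmdmc.trajectory import Trajectory

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_system():
    return m.default_system()


@pytest.fixture(scope="session")
def desk():
    return m.desk_system()


@pytest.fixture
def toy_trajectory():
    """Two particles, four frames in a 10 A box, hand-placed coordinates."""
    pos = np.array([
        [[0.2, 0.2, 0.2], [5.1, 5.1, 5.1]],
        [[0.7, 0.2, 0.2], [5.1, 5.1, 9.9]],
        [[0.7, 0.7, 0.2], [5.1, 5.1, 0.1]],
        [[0.2, 0.7, 0.2], [5.1, 5.1, 0.1]],
    ])
    return Trajectory(pos, ["A", "B"], (10.0, 10.0, 10.0),
                      frame_interval=0.5)


@pytest.fixture(scope="session")
def free_trajectory():
    """Interaction-free particles diffusing in a periodic box (no membrane)."""
    from ionmdmc.dynamics import SimParams, run_simulation
    sys_ = m.bulk_system(60, box=(20.0, 20.0, 20.0))
    return run_simulation(sys_, SimParams(n_steps=20_000, record_every=20,
                                          seed=42))
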