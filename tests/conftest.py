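import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def maze():
    from rampscope.maze import MazeModel

    return MazeModel()


@pytest.fixture(scope="session")
def small_session(maze):
    """A modest synthetic session shared by behavior/tuning tests."""
    from rampscope.simulate import SimConfig, simulate_session

    cfg = SimConfig(n_trials=12, rng_seed=5)
    counts = {"uphill": 4, "downhill": 4, "flat": 4, "quiescent": 4}
    return simulate_session(maze, cfg, counts, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
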