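import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def short_session(rng):
    """A 300 s simulated task session with default parameters."""
    import lickcraft as lc

    return lc.simulate_task_session(
        lc.TaskConfig(session_duration=300.0), lc.LickTrainParams(), rng
    )
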