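import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_train(times_s, t_stop=None, t_start=0.0):
    """Convenience SpikeTrain constructor for hand-built fixtures."""
    from shockresp import SpikeTrain

    times = np.asarray(times_s, dtype=float)
    if t_stop is None:
        t_stop = float(times[-1]) + 0.001 if times.size else 1.0
    return SpikeTrain(times, t_start=t_start, t_stop=t_stop)


@pytest.fixture
def train_factory():
    return make_train
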