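import numpy as np
import pytest

from dalan.simulator import SimulationConfig, build_simulation
from dalan.survival import SurvivalRecord


@pytest.fixture(scope="session")
def small_digit_dataset():
    """One small two-ROI digit cohort shared by training smoke tests."""
    return build_simulation(SimulationConfig(n_patients=120, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_records(rng, n, censor_p=0.4):
    times = rng.uniform(0.1, 10.0, size=n)
    events = (rng.random(n) > censor_p).astype(int)
    if events.sum() == 0:
        events[0] = 1
    return [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]
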