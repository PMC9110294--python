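import numpy as np
import pytest

import mrnakinetics as mk

TRUTH = {
    "theta1": 0.2, "theta2": 0.32, "theta3": 0.01,
    "m0": 240.0, "t0": 0.96, "scale": 1.8, "offset": 6.5, "sigma": 0.0,
}


@pytest.fixture(scope="session")
def fixture_noise_free():
    """One noise-free benchmark trajectory (181 frames, 30 h)."""
    return mk.benchmark_fixture(with_noise=False, seed=1)


@pytest.fixture(scope="session")
def fixture_noisy():
    return mk.benchmark_fixture(with_noise=True, seed=1)


@pytest.fixture(scope="session")
def truth():
    return dict(TRUTH)
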