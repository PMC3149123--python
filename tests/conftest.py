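import numpy as np
import pytest

from mitopulse import fit_baseline
from mitopulse.simulate import TraceSimConfig, simulate_trace


@pytest.fixture(scope="session")
def noiseless_baseline_trace():
    """Pure Weibull baseline, no pulses, no noise: the fit oracle input."""
    cfg = TraceSimConfig(pulses=(), poisson_noise=False, seed=0)
    return simulate_trace(cfg)


@pytest.fixture(scope="session")
def maturing_trace():
    """One default maturing-preset trace with Poisson noise."""
    return simulate_trace(TraceSimConfig(seed=7))


@pytest.fixture(scope="session")
def maturing_fit(maturing_trace):
    return fit_baseline(maturing_trace)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
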