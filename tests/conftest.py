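import numpy as np
import pytest

import smassembly as sm


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the HMM kernels once so per-test timings are meaningful."""
    params = sm.FretSimParams(k_f=0.5, k_d=0.5, duration=5.0, seed=0)
    trace, _ = sm.simulate_fret_trace(params)
    sm.fit_two_state_hmm(trace.efficiency, max_iter=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dynamic_fret_trace():
    """A 200 s trace with plenty of binding/unbinding events."""
    params = sm.FretSimParams(k_f=0.1, k_d=0.2, seed=42,
                              initial_state="stationary-random")
    return sm.simulate_fret_trace(params)
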