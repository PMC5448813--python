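import numpy as np
import pytest

from bistablepc.cohort import build_session, simulate_subject
from bistablepc.model import ModelParams


@pytest.fixture(scope="session")
def small_session():
    """One run of two ambiguous/replay block pairs at 0.30 Hz."""
    return build_session(0.30, runs=1, pairs_per_run=2)


@pytest.fixture(scope="session")
def small_subject(small_session):
    """Simulated responses of one observer on the small session."""
    params = ModelParams(pi_init=3.5, pi_stereo=5.0)
    responses, filled = simulate_subject(params, small_session, seed=42)
    return params, responses, filled


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
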