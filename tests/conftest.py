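import warnings

import numpy as np
import pytest

from phasecode.field_model import FieldParams, InputSpec, simulate_field
from phasecode.synthetic import SessionConfig, generate_session

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def default_params() -> FieldParams:
    return FieldParams()


@pytest.fixture(scope="session")
def osc_trace(default_params):
    """A single default-condition oscillating run (8 s, OU noise on)."""
    return simulate_field(default_params, InputSpec(), duration=8000.0,
                          seed=5).after_transient()


@pytest.fixture(scope="session")
def quiet_trace(default_params):
    """Noise-free, subthreshold run: converges to the fixed point."""
    p = default_params.replace(Ie0=default_params.Ie0 - 0.2,
                               Ii0=default_params.Ii0 - 0.2, sigma_z=0.0)
    return simulate_field(p, InputSpec(a=0, b=0), duration=2000.0,
                          seed=1).after_transient()


@pytest.fixture(scope="session")
def session10():
    """Default synthetic session, 10 trials per condition x stimulus."""
    return generate_session(SessionConfig(n_trials=10, seed=2))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
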