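import numpy as np
import pytest

from ecgstress.synthetic import (BeatParams, mental_arithmetic_protocol,
                                 simulate_cohort)
from ecgstress.workflows import simulate_windows

# strongly separable condition parameters used by the learning tests
REST_STRONG = BeatParams(mean_hr=60, sdnn=55, respiratory_mod_hz=0.25)
STRESS_STRONG = BeatParams(mean_hr=95, sdnn=20, respiratory_mod_hz=0.35)


@pytest.fixture(scope="session")
def ma_cohort_17():
    """Full-protocol 17-subject mental-arithmetic cohort (Table-2 scale)."""
    return simulate_cohort(mental_arithmetic_protocol(), 17, cohort_seed=42)


@pytest.fixture(scope="session")
def small_ma_windows():
    """Shortened-protocol 6-subject cohort, 10 s windows (fast learning set)."""
    proto = mental_arithmetic_protocol(segment_s=150.0)
    return simulate_windows(proto, 6, 10, cohort_seed=11,
                            rest_params=REST_STRONG,
                            stress_params=STRESS_STRONG)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
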