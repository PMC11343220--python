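import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spectraldwi as sd

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bvalues():
    return sd.DEFAULT_BVALUES.copy()


@pytest.fixture(scope="session")
def mean_components():
    """Three Gaussian components at the cohort's distribution means."""
    return [
        sd.ComponentParams(0.6, 0.0015),
        sd.ComponentParams(0.3, 0.010),
        sd.ComponentParams(0.1, 0.070),
    ]


@pytest.fixture(scope="session")
def mean_curve(mean_components, bvalues):
    return sd.gaussian_signal(mean_components, bvalues)


@pytest.fixture(scope="session")
def small_cohort3():
    return sd.simulate_cohort(sd.CohortConfig(n_sets=40, master_seed=123))


@pytest.fixture(scope="session")
def small_cohort2():
    return sd.simulate_cohort(
        sd.CohortConfig(n_sets=40, n_components=2, master_seed=456))
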