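import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as st

import patlaksim as ps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FIXTURE_NAMES = ["huJ591-like", "trastuzumab-like", "pertuzumab-like"]


@pytest.fixture(params=FIXTURE_NAMES)
def fixture_ifn(request):
    return ps.fixture_library(request.param)


@pytest.fixture
def all_fixtures():
    return [ps.fixture_library(n) for n in FIXTURE_NAMES]


@pytest.fixture
def default_schedule():
    return ps.SamplingSchedule.from_imaging_times([24.0, 48.0, 96.0])


@pytest.fixture
def all_schedules():
    return ps.enumerate_schedules()


def input_functions(min_amp=0.5, max_amp=60.0):
    """Strategy for valid bi-exponential input functions with both phases."""
    return st.builds(
        ps.InputFunction,
        amp_fast=st.floats(min_amp, max_amp),
        rate_fast=st.floats(-0.5, -0.02),
        amp_slow=st.floats(min_amp, max_amp),
        rate_slow=st.floats(-0.02, -0.002, exclude_max=True),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20221024)
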