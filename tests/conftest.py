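import pytest
from hypothesis import HealthCheck, settings

from leadtime import ScreeningSchedule, StableDiseaseParams, load_trials

settings.register_profile(
    "unit",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("unit")


@pytest.fixture(scope="session")
def trials():
    return load_trials()


@pytest.fixture
def hip():
    """HIP trial parameters with the default transition rate."""
    return StableDiseaseParams(w=0.004, beta=0.70, lam=2.50)


@pytest.fixture
def edinburgh():
    return StableDiseaseParams(w=0.004, beta=0.78, lam=4.30)


@pytest.fixture
def annual_program():
    """Annual exams from age 50 to 80 (K = 30)."""
    return ScreeningSchedule(t0=50.0, T=80.0, delta=1.0)


@pytest.fixture
def small_program():
    """Tiny 3-exam program for quadrature cross-checks."""
    return ScreeningSchedule(t0=4.0, T=10.0, delta=2.0)
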