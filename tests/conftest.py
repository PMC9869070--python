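import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from silagegwp import compute_breakdowns, generate_mock_cohort, load_voc_table


@pytest.fixture(scope="session")
def voc_table():
    return load_voc_table()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: 1,000 profiles, seed 0."""
    return generate_mock_cohort(n=1000, seed=0)


@pytest.fixture(scope="session")
def breakdowns(cohort):
    return compute_breakdowns(cohort.frame)
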