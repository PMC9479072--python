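import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def base_params():
    from cohortcea import default_parameters

    return default_parameters()


@pytest.fixture(scope="session")
def base_results():
    """Base-case fit shared across tests (read-only)."""
    from cohortcea import CostUtilityModel

    return CostUtilityModel().fit()
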