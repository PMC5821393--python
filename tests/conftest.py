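import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sthpd_cea import (
    default_parameters,
    early_intervention_scenario,
    usual_care_scenario,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def usual_care(params):
    return usual_care_scenario(params)


@pytest.fixture(scope="session")
def early_intervention(params):
    return early_intervention_scenario(params)
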