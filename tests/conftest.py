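import pytest

from iwb.core_index import ElasticityVector
from iwb.scenarios_io import baseline_scenarios


@pytest.fixture(scope="session")
def fixtures():
    return baseline_scenarios()


@pytest.fixture(scope="session")
def straddle(fixtures):
    return fixtures["threshold-straddling"]


@pytest.fixture(scope="session")
def steady(fixtures):
    return fixtures["steady-midlife"]


@pytest.fixture
def theta_half():
    return ElasticityVector({"financial": 0.5, "physical": 0.5})
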