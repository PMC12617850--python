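import pytest

from sideroscan.screen import screen_siderophores
from sideroscan.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def default_scenario():
    """The default planted scenario at seed 1, shared across tests."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def default_candidates(default_scenario):
    return screen_siderophores(default_scenario.sample, default_scenario.control)
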