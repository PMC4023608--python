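import pytest

from srfpipe.fixtures import make_paper_fixtures
from srfpipe.simulate import SimulationParams, simulate_genome


@pytest.fixture(scope="session")
def paper_fixtures():
    return make_paper_fixtures()


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams()


@pytest.fixture(scope="session")
def small_genome(default_params):
    """One deterministic synthetic genome shared across read-only tests."""
    return simulate_genome(default_params, seed=7)
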