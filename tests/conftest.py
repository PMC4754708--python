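import pytest

from mitocomp.synthetic_data import SimulationSpec, simulate_mitogenome


@pytest.fixture(scope="session")
def default_sim():
    """One deterministic synthetic mitogenome shared across the suite."""
    return simulate_mitogenome(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def genome(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def truth(default_sim):
    return default_sim[1]
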