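import pytest

from paleomem.simulate import SimConfig, generate_scenario


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale-but-smaller scenario used by unit tests."""
    return SimConfig(
        n_genomes=12, n_lineages=4, n_families=300, n_cassettes=4
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config, seed=11)


@pytest.fixture(scope="session")
def default_scenario():
    """One full default-condition scenario, shared across tests."""
    return generate_scenario(seed=42)
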