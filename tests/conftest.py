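import pytest

from ahasim import WorldConfig, default_architecture, random_genome
from ahasim.experiments import evolve_scenario_population
from ahasim.rng import child_rng


@pytest.fixture(scope="session")
def arch():
    return default_architecture()


@pytest.fixture()
def genome(arch):
    return random_genome(arch, child_rng(42, "fixture-genome"))


@pytest.fixture()
def world_config():
    return WorldConfig()


@pytest.fixture(scope="session")
def scenario_population():
    """One small adapted population shared by every scenario-level test."""
    return evolve_scenario_population(seed=11)
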