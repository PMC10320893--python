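"""Shared fixtures: synthetic worlds and field providers (built once)."""

import numpy as np
import pytest

from magmigrate.scenarios import scenario_barrier_world, scenario_uniform_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def barrier_scenario():
    return scenario_barrier_world()


@pytest.fixture(scope="session")
def barrier_world(barrier_scenario):
    world = barrier_scenario.build_world(seed=1)
    world.cell_coast_distance_km  # warm the detection prefilter cache
    return world


@pytest.fixture(scope="session")
def barrier_field(barrier_scenario):
    return barrier_scenario.field_provider()


@pytest.fixture(scope="session")
def uniform_scenario():
    return scenario_uniform_field()


@pytest.fixture(scope="session")
def uniform_world(uniform_scenario):
    world = uniform_scenario.build_world(seed=3)
    world.cell_coast_distance_km
    return world


@pytest.fixture(scope="session")
def uniform_field(uniform_scenario):
    return uniform_scenario.field_provider()
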