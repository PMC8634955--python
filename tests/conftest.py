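"""Shared fixtures: synthetic input bundles and toy demographic scaffolding."""

import numpy as np
import pytest

from prrpsim import (
    DemographySchedules,
    FixtureSpec,
    LifeTable,
    StateSpace,
    generate_fixtures,
)
from prrpsim.demography import N_AGES


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def bundle(fixture_spec):
    return generate_fixtures(fixture_spec)


@pytest.fixture(scope="session")
def space1() -> StateSpace:
    return StateSpace(("cigarette",))


@pytest.fixture(scope="session")
def space2() -> StateSpace:
    return StateSpace(("cigarette", "prrp"))


@pytest.fixture(scope="session")
def space3() -> StateSpace:
    return StateSpace(("cigarette", "ecig", "thp"))


@pytest.fixture()
def zero_mortality_life_table() -> LifeTable:
    """No deaths below age 100 — isolates non-mortality mechanics."""
    m = np.zeros((2, N_AGES))
    m[:, -1] = 1.0
    return LifeTable({2001: m}, life_expectancy=np.zeros((2, N_AGES)))


@pytest.fixture()
def empty_schedules() -> DemographySchedules:
    return DemographySchedules()
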