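import numpy as np
import pytest

from platewaste import (
    CompetitiveImpactConfig,
    MealPortion,
    MenuConfig,
    PopulationConfig,
    SimulationConfig,
    WasteFractionConfig,
)
from platewaste.population import Child


@pytest.fixture
def rng():
    return np.random.default_rng(20220587)


@pytest.fixture
def menu_cfg():
    return MenuConfig()


@pytest.fixture
def pop_cfg():
    return PopulationConfig()


@pytest.fixture
def waste_cfg():
    return WasteFractionConfig()


@pytest.fixture
def competitive_cfg():
    return CompetitiveImpactConfig()


@pytest.fixture
def fixed_portion():
    """A plausible MS-day portion with every component present except milk."""
    return MealPortion(m=200.0, s=175.0, sd=30.0, ld=150.0, b=25.0, fp=75.0, mk=0.0)


def make_child(vs=35.0, ef=0, u=0, hated=(0, 0, 0, 0, 0), stops=1):
    return Child(vs=vs, vl=2 * vs, ef=ef, u=u, hated_days=tuple(hated),
                 stops_when_out_of_time=stops)


@pytest.fixture
def small_cfg():
    """A reduced-repetition simulation config for fast end-to-end tests."""
    return SimulationConfig(repetitions=300, seed=11)
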