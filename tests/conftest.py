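import numpy as np
import pytest

from operat.instrument import AreaAssessment, load_default_instrument
from operat.synthetic import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def spec():
    return load_default_instrument()


@pytest.fixture(scope="session")
def bundle():
    """One full-size synthetic study bundle shared across tests."""
    return simulate_bundle(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced bundle for tests that only need structure, not power."""
    return simulate_bundle(
        SimulationConfig(seed=5, n_areas=80, n_resident_returns=150,
                         ineligible_counts=(10, 8, 4, 3),
                         n_weighting_respondents=60)
    )


def make_assessment(spec, level: float, area_id: str = "A1") -> AreaAssessment:
    """An assessment with every item at a given recoded badness level in [0,1]."""
    obs = {}
    for it in spec.items:
        if it.value_kind == "binary":
            v = round(level)
            raw = 1 - v if it.desirable_direction == "presence_good" else v
        elif it.value_kind == "proportion":
            raw = 1 - level if it.desirable_direction == "presence_good" else level
        else:
            idx = round(level * (it.ordinal_levels - 1))
            raw = (
                it.ordinal_levels - 1 - idx
                if it.desirable_direction == "presence_good"
                else idx
            )
        obs[it.item_id] = float(raw)
    return AreaAssessment(area_id=area_id, observations=obs)


def random_assessment(spec, rng: np.random.Generator, area_id: str = "R1") -> AreaAssessment:
    obs = {}
    for it in spec.items:
        if it.value_kind == "binary":
            obs[it.item_id] = float(rng.integers(0, 2))
        elif it.value_kind == "proportion":
            obs[it.item_id] = float(rng.uniform())
        else:
            obs[it.item_id] = float(rng.integers(0, it.ordinal_levels))
    return AreaAssessment(area_id=area_id, observations=obs)
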