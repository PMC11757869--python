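import numpy as np
import pytest

from echonav import ConfidenceMap, GridGeometry, RewardParams
from echonav.confmap import MapGenParams, generate_cohort


class ScriptedAgent:
    """Planner-compatible agent returning canned Q-vectors.

    ``table`` maps a cell to a 9-vector; ``default`` covers everything else.
    """

    def __init__(self, table=None, default=None):
        self.table = table or {}
        self.default = np.zeros(9) if default is None else np.asarray(default, float)

    def action_values(self, position, c_here):
        return np.asarray(self.table.get(position, self.default), dtype=float)


@pytest.fixture
def scripted_agent_cls():
    return ScriptedAgent


@pytest.fixture
def geometry():
    return GridGeometry(7, 5)


@pytest.fixture
def reward_params():
    return RewardParams()


@pytest.fixture
def map3x3():
    """3x3 map, strictly positive, unique maximum at (1, 2)."""
    c = np.array(
        [
            [0.10, 0.20, 0.30],
            [0.15, 0.40, 0.90],
            [0.05, 0.25, 0.60],
        ]
    )
    return ConfidenceMap("unit-3x3", GridGeometry(3, 3), c)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale synthetic cohort: 24 subjects, default chest model."""
    return generate_cohort(MapGenParams(), 24, seed=7)


def random_map(rng, n_x=3, n_y=3, low=0.05, high=0.95):
    """Random strictly-positive map with a unique global maximum."""
    while True:
        c = rng.uniform(low, high, (n_x, n_y))
        if np.count_nonzero(c == c.max()) == 1:
            return ConfidenceMap(f"rand-{rng.integers(1 << 30)}", GridGeometry(n_x, n_y), c)
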