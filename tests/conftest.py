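import numpy as np
import pytest

from clsmeta.evaluation import WeightScheme, make_weights
from clsmeta.harmonize import ScreenDataset
from clsmeta.outranking import CriteriaMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_screens():
    """Three tiny screens over a partially overlapping gene universe."""
    return [
        ScreenDataset("s1", {"YAL001C": 3.0, "YAL002W": 2.0, "YAL003W": 1.0}),
        ScreenDataset("s2", {"YAL002W": 5.0, "YAL003W": 4.0, "YAL004W": 6.0}),
        ScreenDataset("s3", {"YAL003W": 0.1, "YAL005W": 0.2}),
    ]


def random_criteria_matrix(rng, n_alt=None, n_crit=None, missing=0.2):
    """Random PROMETHEE instance with a missingness mask (every gene keeps
    at least one observed criterion)."""
    n_alt = n_alt or int(rng.integers(3, 51))
    n_crit = n_crit or int(rng.integers(1, 6))
    values = rng.normal(size=(n_alt, n_crit))
    # duplicate some values to exercise ties
    if n_alt > 4:
        values[1, :] = values[0, :]
    mask = rng.random(size=values.shape) < missing
    for i in range(n_alt):
        if mask[i].all():
            mask[i, rng.integers(n_crit)] = False
    values[mask] = np.nan
    raw = rng.random(n_crit) + 0.1
    weights = WeightScheme(
        weights={f"c{j}": w for j, w in enumerate(raw / raw.sum())}, scheme="priority"
    )
    return CriteriaMatrix(
        alternatives=[f"G{i:03d}" for i in range(n_alt)],
        criteria=[f"c{j}" for j in range(n_crit)],
        values=values,
        weights=weights,
    )


@pytest.fixture
def equal_weights_5():
    return make_weights([f"d{i}" for i in range(5)], scheme="equal")
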