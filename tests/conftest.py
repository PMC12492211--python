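import numpy as np
import pandas as pd
import pytest

from evorescue import hybrid_params, relative_fitness, standardize_trait
from evorescue.selection import TRAIT_COLUMN


@pytest.fixture
def four_plant_table() -> pd.DataFrame:
    """Minimal one-site table: traits 1..4, the two thin-leaved plants die."""
    return pd.DataFrame(
        {
            "plant_id": ["a", "b", "c", "d"],
            "site": ["hyb"] * 4,
            "year": [2010] * 4,
            TRAIT_COLUMN: [1.0, 2.0, 3.0, 4.0],
            "survival": [1, 1, 0, 0],
        }
    )


@pytest.fixture
def prepared_four(four_plant_table) -> pd.DataFrame:
    return relative_fitness(standardize_trait(four_plant_table))


@pytest.fixture
def hybrid():
    return hybrid_params()


def random_table(rng: np.random.Generator, n: int = 50, sites=("agg", "hyb")) -> pd.DataFrame:
    """Random trait/survival table with no built-in trait-fitness link."""
    return pd.DataFrame(
        {
            "plant_id": [f"p{i}" for i in range(n)],
            "site": rng.choice(sites, n),
            "year": 2010,
            TRAIT_COLUMN: rng.normal(250, 25, n),
            "survival": rng.integers(0, 2, n),
        }
    )
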