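import numpy as np
import pandas as pd
import pytest

from pelagifd.space import gower, pcoa
from pelagifd.synthetic import CommunitySpec, generate_pool


@pytest.fixture(scope="session")
def pool42():
    """Reference-sized synthetic species pool (42 species, 26 traits)."""
    return generate_pool(CommunitySpec(seed=1))


@pytest.fixture(scope="session")
def space42(pool42):
    """4-axis functional space built from the pool archetypes."""
    D = gower(pool42.traits)
    sp = pcoa(D, correction="sqrt")
    sp.m = 4
    return sp


@pytest.fixture(scope="session")
def gower42(pool42):
    return gower(pool42.traits)


@pytest.fixture()
def mixed_matrix():
    """Tiny hand-made mixed-type trait matrix (5 species)."""
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {
            "c1": [0.1, 0.4, 0.2, 0.9, 0.5],
            "c2": [1.0, 2.0, 1.5, 0.5, 2.5],
            "o1": [0, 1, 2, 1, 0],
            "b1": [0, 1, 0, 1, 1],
            "b2": [1, 1, 0, 0, 1],
        },
        index=[f"sp{i}" for i in range(5)],
        dtype=float,
    )
    return df, {"c1": "continuous", "c2": "continuous", "o1": "ordinal",
                "b1": "binary", "b2": "binary"}
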