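import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from grainbeta.community import AbundanceMatrix  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20150714)


@pytest.fixture
def toy_counts():
    """Four plots x five species, two habitats, with one singleton (spE)."""
    df = pd.DataFrame(
        [
            [8, 2, 0, 1, 0],
            [6, 4, 1, 0, 0],
            [0, 3, 7, 2, 1],
            [1, 0, 9, 3, 0],
        ],
        index=["op1", "op2", "fo1", "fo2"],
        columns=["spA", "spB", "spC", "spD", "spE"],
    )
    return AbundanceMatrix(df, "count")


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {
            "habitat": ["oil_palm", "oil_palm", "forest", "forest"],
            "block": ["b1", "b1", "b2", "b2"],
            "latitude": [5.0, 5.01, 5.5, 5.51],
            "longitude": [117.0, 117.01, 117.5, 117.51],
            "year": [2011, 2011, 2012, 2012],
        },
        index=pd.Index(["op1", "op2", "fo1", "fo2"], name="sample_id"),
    )


def random_community(rng, n_species=None, sparsity=0.5):
    """A random relative-abundance vector with some structural zeros."""
    s = n_species or int(rng.integers(3, 40))
    p = rng.dirichlet(np.full(s, 0.5))
    mask = rng.random(s) < sparsity
    if mask.all():
        mask[rng.integers(0, s)] = False
    p = np.where(mask, 0.0, p)
    return p / p.sum()
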