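import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gamma_sample(rng):
    """A single right-skewed positive trait sample."""
    return rng.gamma(4.0, 10.0, size=50)


@pytest.fixture
def small_pool(rng):
    """A quick contaminated pool (reduced counts) for engine tests."""
    from traitcv.simulation import PoolConfig, add_extremes, generate_base_pool

    cfg = PoolConfig(shape=4.0, scale=10.0, n_base=952, n_extreme=48)
    base = generate_base_pool(cfg, rng)
    return add_extremes(base, cfg, rng)


@pytest.fixture
def trait_table():
    """Tiny tidy trait table with two species x two traits."""
    rng = np.random.default_rng(7)
    rows = []
    for species in ("sp1", "sp2"):
        for trait in ("sla", "height"):
            for v in rng.gamma(5.0, 3.0, size=60):
                rows.append({"species": species, "trait": trait, "value": v})
    return pd.DataFrame(rows)
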