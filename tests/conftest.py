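import numpy as np
import pytest

from lusa.landuse import default_shares, to_canonical
from lusa.synthetic import (
    env_stack,
    generate_landscape,
    generate_reference_tables,
    generate_scenario,
    ssp1_like,
)


@pytest.fixture(scope="session")
def cfg():
    """Small, fast scenario configuration shared across tests."""
    return ssp1_like(grid_shape=(20, 20), seed=11, n_species=3,
                     n_pseudo_absences=300)


@pytest.fixture(scope="session")
def landscape(cfg):
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def raw_grids(cfg):
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def canonical_grids(raw_grids):
    shares = default_shares()
    return [to_canonical(g, shares) for g in raw_grids]


@pytest.fixture(scope="session")
def refs(cfg, landscape):
    """(carbon_refs, price_table, crop_yields, pasture_yields)."""
    return generate_reference_tables(cfg, landscape)


@pytest.fixture(scope="session")
def base_env(canonical_grids, landscape):
    return env_stack(canonical_grids[0], landscape)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
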