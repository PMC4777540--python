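import numpy as np
import pytest

from mupscent.profiles import (
    SiteRecord,
    VariantProfileMatrix,
    load_combined_tables,
    load_nonsynonymous_table,
    load_synonymous_table,
)


@pytest.fixture(scope="session")
def nonsyn_table():
    return load_nonsynonymous_table()


@pytest.fixture(scope="session")
def syn_table():
    return load_synonymous_table()


@pytest.fixture(scope="session")
def combined_tables():
    return load_combined_tables()


def random_profile_matrix(rng, n_individuals=5, n_sites=6, site_class=None):
    """A random valid profile matrix for property tests."""
    sites = [
        SiteRecord(coordinate=f"chr4:{1000 + i}", site_class=site_class)
        for i in range(n_sites)
    ]
    values = rng.uniform(0, 100, size=(n_sites, n_individuals))
    # sprinkle zeros so carrier counts vary
    values[rng.random(values.shape) < 0.3] = 0.0
    ids = [f"M{j}" for j in range(n_individuals)]
    return VariantProfileMatrix(ids, sites, values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
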