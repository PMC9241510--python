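import numpy as np
import pandas as pd
import pytest

import guildnet as gn


@pytest.fixture(scope="session")
def sites_small() -> pd.DataFrame:
    return gn.generate_sites(60, seed=0)


@pytest.fixture(scope="session")
def sites_medium() -> pd.DataFrame:
    return gn.generate_sites(200, seed=0)


@pytest.fixture()
def bernoulli_occ():
    """Independent Bernoulli(0.5) occurrence matrix (no structure at all)."""

    def make(n_species: int, n_sites: int, seed: int = 0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        mat = (rng.random((n_species, n_sites)) < 0.5).astype(np.int8)
        return pd.DataFrame(
            mat,
            index=[f"s{i}" for i in range(n_species)],
            columns=[f"site{j}" for j in range(n_sites)],
        )

    return make
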