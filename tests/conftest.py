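import numpy as np
import pytest

from modalign.synthetic import (EmbeddingSpec, UniverseConfig,
                                generate_embedding_pairs,
                                generate_protein_universe, split_dataset)


@pytest.fixture(scope="session")
def small_universe():
    return UniverseConfig(n_base_proteins=40, homology_cluster_count=6,
                          master_seed=7)


@pytest.fixture(scope="session")
def small_table(small_universe):
    return generate_protein_universe(small_universe)


@pytest.fixture(scope="session")
def small_dataset(small_universe, small_table):
    ds = generate_embedding_pairs(
        small_table, EmbeddingSpec(latent_dim=8, graph_dim=24, text_dim=32),
        seed=small_universe.master_seed)
    return split_dataset(ds, seed=small_universe.master_seed)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
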