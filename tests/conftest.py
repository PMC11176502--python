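import numpy as np
import pytest

from mdassoc import graph_data as gd
from mdassoc import similarity as sim


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-block dataset shared across module tests."""
    cfg = gd.SyntheticConfig(
        n_microbes=24,
        n_drugs=36,
        n_blocks=3,
        within_block_density=0.4,
        background_density=0.03,
        sequence_length=60,
        mutation_rate=0.05,
        seed=42,
    )
    return gd.generate_synthetic(cfg)


@pytest.fixture(scope="session")
def small_mss(small_dataset):
    return sim.sequence_similarity_matrix(small_dataset.sequences)


@pytest.fixture(scope="session")
def block_graph(small_dataset, small_mss):
    """Entity graphs binarized at thresholds matched to the synthetic scale,
    so the adjacency actually carries the planted block structure."""
    mg, dg, ms, ds = sim.build_entity_graphs(
        small_dataset.associations,
        small_mss,
        small_dataset.drug_similarity,
        microbe_threshold=0.45,
        drug_threshold=0.45,
    )
    return mg, dg, ms, ds


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
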