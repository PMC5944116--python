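import numpy as np
import pytest

from microdynet import (
    NetworkTopology,
    SimConfig,
    TrainingConfig,
    simulate_dynamics,
)
from microdynet.synthetic_data import default_interaction_matrix


@pytest.fixture
def small_sim_config():
    """5 taxa, 2 substrates, mild interactions, no noise."""
    rng = np.random.default_rng(42)
    A = default_interaction_matrix(5, 2, driver_indices=(0, 1),
                                   n_edges_per_driver=2, seed=42) * 0.3
    return SimConfig(
        n_taxa=5,
        n_substrates=2,
        sampling_days=(0, 1, 2, 3, 7, 14),
        replicates_per_timepoint=2,
        interaction_matrix=A,
        baseline_abundances=rng.dirichlet(np.ones(5) * 4),
        noise_sd=0.0,
        driver_indices=(0, 1),
        seed=42,
    )


@pytest.fixture
def small_dataset(small_sim_config):
    return simulate_dynamics(small_sim_config)


@pytest.fixture
def tiny_topology():
    return NetworkTopology(n_taxa=3, n_substrates=1)


@pytest.fixture
def fast_training():
    return TrainingConfig(max_epochs=200, seed=7)


@pytest.fixture
def toy_otu_table_text():
    """3 OTUs x 2 samples, classic layout."""
    return (
        "# Constructed from observation data\n"
        "#OTU ID\tS1\tS2\ttaxonomy\n"
        "OTU1\t10\t0\tk__Bacteria; p__P1; c__C1; o__Alpha; f__; g__; s__\n"
        "OTU2\t30\t50\tk__Bacteria; p__P1; c__C1; o__Alpha; f__; g__; s__\n"
        "OTU3\t60\t50\tk__Bacteria; p__P2; c__C2; o__Beta; f__; g__; s__\n"
    )


@pytest.fixture
def toy_metadata_text():
    return (
        "sample_id\tdiet\tday\n"
        "S1\tmulch\t0\n"
        "S2\tmulch\t7\n"
    )


@pytest.fixture
def toy_table(tmp_path, toy_otu_table_text, toy_metadata_text):
    from microdynet import read_otu_table

    otu = tmp_path / "otu.tsv"
    meta = tmp_path / "meta.tsv"
    otu.write_text(toy_otu_table_text)
    meta.write_text(toy_metadata_text)
    return read_otu_table(otu, meta)
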