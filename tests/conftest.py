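import numpy as np
import pytest

from introdepth import SimulationConfig, simulate_alignments, simulate_gene_trees


@pytest.fixture(scope="session")
def small_dataset():
    """A small introgression dataset shared by pipeline-level tests."""
    config = SimulationConfig(
        tau1=1.0,
        tau2=5.0,
        tau_out=8.0,
        gamma=0.3,
        t_gamma=0.5,
        donor_recipient=("C", "A"),
        n_loci=150,
        seq_length=1200,
        theta=0.02,
        seed=20240917,
    )
    loci = simulate_alignments(simulate_gene_trees(config), config)
    return config, loci


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
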