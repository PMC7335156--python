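import numpy as np
import pytest

from seedmeth import simulate
from seedmeth.io import GenomeAssembly


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        seed=11, n_chromosomes=1, chromosome_length=120_000,
        chloroplast_length=30_000, n_genes=10, n_tes=8,
        stages=("S1", "S2"), depth_mean=10, n_replicates=2)


@pytest.fixture(scope="session")
def small_world(small_config):
    """Genome, features, default landscape, shared truth, one sample."""
    genome, features = simulate.generate_genome(small_config)
    landscape = simulate.MethylationLandscape()
    truth, gene_truth = simulate.methylome_truth(
        genome, features, landscape, small_config)
    sample = simulate.simulate_methylome(
        genome, truth, landscape, small_config, "S1")
    return {"genome": genome, "features": features, "landscape": landscape,
            "truth": truth, "gene_truth": gene_truth, "sample": sample,
            "config": small_config}


@pytest.fixture()
def toy_genome():
    return GenomeAssembly(
        {"chr1": "ACGATCAGCTTCGGCANCGT", "pt": "ATCGATCG"},
        chloroplast_name="pt")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
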