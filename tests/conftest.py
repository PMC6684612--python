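import warnings

import pytest

from myelosig import synthetic as syn

warnings.filterwarnings("ignore", message="Maximum number of iterations")


@pytest.fixture(scope="session")
def small_config():
    return syn.SimulationConfig(
        seed=7,
        n_samples=25,
        mutations_per_sample=250,
        contig_sizes={"chr1": 400_000, "chr2": 400_000},
        n_genes=80,
    )


@pytest.fixture(scope="session")
def genome(small_config):
    return syn.simulate_genome(small_config)


@pytest.fixture(scope="session")
def cohort(small_config, genome):
    muts, exposures = syn.simulate_mutations(small_config, genome)
    return muts, exposures
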