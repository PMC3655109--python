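import numpy as np
import pytest

from mhcamplicon import simulate as sim


@pytest.fixture(scope="session")
def small_pool():
    """Six distinct 36-bp stop-free alleles."""
    return sim.generate_allele_pool(n_alleles=6, length=36, divergence=0.15, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(small_pool):
    """Error-free reads for 6 individuals carrying 1-3 alleles each."""
    design = sim.PopulationDesign(
        n_individuals=6, copies_per_individual={1: 0.3, 2: 0.4, 3: 0.3}
    )
    rng = np.random.default_rng(21)
    genotypes = sim.assign_genotypes(small_pool, design, seed=rng)
    sheet = sim.make_sample_sheet(sorted(genotypes), seed=rng)
    err = sim.ErrorModel(
        substitution_rate=0.0,
        homopolymer_indel_rate=0.0,
        chimera_rate=0.0,
        reads_per_replicate=12,
    )
    truth = sim.simulate_reads(genotypes, small_pool, sheet, err, seed=rng)
    return small_pool, genotypes, sheet, truth
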