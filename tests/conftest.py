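import pytest

from retrokit import synthetic_data as syn


@pytest.fixture(scope="session")
def toy_genome():
    """One 1-Mbp chromosome with 10 genes and enhancers."""
    return syn.gen_toy_genome(n_chrom=1, chrom_len=1_000_000, n_genes=10, seed=1)


@pytest.fixture(scope="session")
def two_chrom_genome():
    return syn.gen_toy_genome(n_chrom=2, chrom_len=500_000, n_genes=12, seed=4)


@pytest.fixture(scope="session")
def donor_gene(toy_genome):
    """A donor transcript with at least 3 exons."""
    return next(t for t in sorted(toy_genome.genes)
                if toy_genome.genes[t].n_exons >= 3)
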