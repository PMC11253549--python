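import numpy as np
import pytest

from crisprpop.synthetic_data import (
    SyntheticGenomeConfig,
    SyntheticVariantConfig,
    generate_genome,
    generate_variants,
)
from crisprpop.genome_io import GenomeSequence

BASES = np.array(list("ACGT"))


def random_genome(length: int, seed: int, gc: float = 0.5, name: str = "chr1") -> GenomeSequence:
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return GenomeSequence({name: "".join(BASES[rng.choice(4, size=length, p=p)])})


@pytest.fixture(scope="session")
def demo_fixture():
    """Two-contig annotated genome with two populations of distinct theta."""
    gcfg = SyntheticGenomeConfig(
        n_contigs=2, contig_length=20_000, n_genes=12, cds_per_gene=2,
        cds_length=400, reverse_strand_fraction=0.3, seed=11,
    )
    genome, models = generate_genome(gcfg)
    vcfg = SyntheticVariantConfig(
        theta={"popA": 0.02, "popB": 0.002}, ref_af=0.97, n_samples=20, seed=11
    )
    table = generate_variants(vcfg, genome)
    return genome, models, table


@pytest.fixture(scope="session")
def demo_sites(demo_fixture):
    return demo_fixture[2].to_sites()
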