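import numpy as np
import pytest

from okit.genome_io import GeneFeature, OrganelleGenome
from okit.synthetic_data import SimConfig, simulate_dataset


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def toy_genome():
    """100 bp circular genome: one forward CDS, one reverse CDS, one tRNA."""
    #           0         1         2         3
    #           0123456789012345678901234567890
    seq = (
        "ATGAAACCCTAA"          # [0,12) CDS geneA (+): ATG AAA CCC TAA
        + "GGGG"                 # spacer
        + "TTACATGGGCAT"         # [16,28) CDS geneB (-): revcomp = ATGCCCATGTAA
        + "CCCCCCCC"             # spacer
        + "GCGCGCGCGCGC"         # [36,48) tRNA
        + "A" * 52
    )
    features = [
        GeneFeature("geneA", "CDS", "+", ((0, 12),)),
        GeneFeature("geneB", "CDS", "-", ((16, 28),)),
        GeneFeature("trnA-ugc", "tRNA", "+", ((36, 48),)),
    ]
    return OrganelleGenome(
        id="TOY1", taxon="Toyus exemplaris", sequence=seq, features=features
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """Small simulated dataset shared by read-only tests."""
    config = SimConfig(
        seed=424242, n_genes=25, loss_rate=0.04, gain_prob=0.5,
        dcj_ops_per_branch=1,
    )
    genomes, truth = simulate_dataset(config)
    return config, genomes, truth


@pytest.fixture(scope="session")
def collinear_dataset():
    """Rearrangement-free simulated dataset for identity-scan tests."""
    config = SimConfig(
        seed=77, n_genes=20, loss_rate=0.0, gain_prob=0.0,
        dcj_ops_per_branch=0,
    )
    genomes, truth = simulate_dataset(config)
    return config, genomes, truth
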