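import numpy as np
import pytest

from virobead import community as cm


@pytest.fixture(scope="session")
def two_genome_community() -> cm.Community:
    """Two dsDNA genomes with a 12-point GC offset and 5:1 abundance ratio,
    plus a host background genome — the canonical decontamination fixture."""
    rng = np.random.default_rng(11)
    g1 = cm.ViralGenome(
        genome_id="vgA",
        sequence=cm.random_sequence(rng, 40_000, 0.45),
        taxonomy=("r", "k", "p", "c", "famA", "genA"),
    )
    g2 = cm.ViralGenome(
        genome_id="vgB",
        sequence=cm.random_sequence(rng, 35_000, 0.57),
        taxonomy=("r", "k", "p", "c", "famB", "genB"),
    )
    g1 = cm.plant_genes(g1, seed=1)
    g2 = cm.plant_genes(g2, seed=2)
    host = cm.HostGenome(
        genome_id="host", sequence=cm.random_sequence(rng, 200_000, 0.60), abundance=0.05
    )
    return cm.Community(
        genomes=(g1, g2), abundances=(5 / 6, 1 / 6), background_genome=host
    )


@pytest.fixture(scope="session")
def strain_group():
    """Parent genome, six MTase cassettes and six derived strains."""
    rng = np.random.default_rng(5)
    parent = cm.ViralGenome(
        genome_id="parent", sequence=cm.random_sequence(rng, 40_000, 0.45)
    )
    parent = cm.plant_genes(parent, seed=6)
    cassettes = cm.make_mtase_cassettes(6, rng=7)
    strains = cm.spawn_strains(
        parent, n_strains=6, snv_rate=0.005, flexible_cassettes=cassettes, seed=8
    )
    return parent, cassettes, strains
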