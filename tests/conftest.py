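import pytest

from pankit.io import GeneRecord, Proteome
from pankit.simulate import SimConfig, simulate_pangenome


@pytest.fixture(scope="session")
def small_sim():
    """10 genomes, 20 core + 10 accessory families at genus-level identity."""
    return simulate_pangenome(
        SimConfig(n_genomes=10, n_core_families=20, n_accessory_families=10,
                  rng_seed=1)
    )


@pytest.fixture(scope="session")
def nt_sim():
    """Small within-species dataset (high identity) with nt sequences."""
    return simulate_pangenome(
        SimConfig(n_genomes=6, n_core_families=15, n_accessory_families=5,
                  target_identity=0.99, dup_prob=0.0, rng_seed=3)
    )


def make_proteome(genome_id, seqs):
    """Helper: proteome from {gene_id: aa_seq}."""
    return Proteome(
        genome_id=genome_id,
        genes=[
            GeneRecord(gene_id=g, genome_id=genome_id, aa_seq=s)
            for g, s in seqs.items()
        ],
    )
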