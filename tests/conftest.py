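import pytest

from dodderseq.classify import TaxonomyMap, run_cascade
from dodderseq.simulate import SimConfig, simulate_reads, simulate_transcriptomes

# the fixed seed all recovery-style checks run under
RECOVERY_SEED = 1


@pytest.fixture(scope="session")
def default_sim():
    """The standard study conditions: 10,000 single-end 100 bp reads at a
    16.8:1 parasite:host mix, 0.5% substitution errors, ortholog identity
    drawn uniformly from 75-90%."""
    config = SimConfig(seed=RECOVERY_SEED, ortholog_identity=(75.0, 90.0))
    refs = simulate_transcriptomes(config)
    reads, truth = simulate_reads(refs, config, n_reads=10_000)
    return config, refs, reads, truth


@pytest.fixture(scope="session")
def default_cascade(default_sim):
    config, refs, reads, truth = default_sim
    taxonomy = TaxonomyMap(refs.subject_to_family, refs.family_to_species)
    table = run_cascade(
        reads, refs.contigs_a, refs.contigs_b, refs.genus_refs, refs.family_db, taxonomy
    )
    return table


@pytest.fixture(scope="session")
def small_sim():
    """A light mixture for structural tests where scale does not matter."""
    config = SimConfig(
        seed=11,
        n_genes_shared=6,
        n_genes_private_a=3,
        n_genes_private_b=3,
        gene_length=(300, 800),
        ortholog_identity=(75.0, 90.0),
    )
    refs = simulate_transcriptomes(config)
    reads, truth = simulate_reads(refs, config, n_reads=300)
    return config, refs, reads, truth
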