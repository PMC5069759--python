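"""Shared fixtures: a small synthetic community reused across test modules."""

import pytest

from strainscope.synthetic import GeneratorConfig, generate_community


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down community: quick to generate, still structured."""
    return GeneratorConfig(
        seed=11,
        genome_length=40_000,
        contigs_per_genome=40,
        contig_length_mean=6_000,
        contig_length_sd=1_500,
        n_core=8,
        n_free_living=4,
        n_endosymbiont=3,
        n_unassigned=2,
        n_ref_decoys=2,
        gene_length_codons=110,
        n_marker_families=3,
        n_strains=3,
        marker_length_codons=120,
        n_ortholog_pairs=24,
        pair_codons=150,
        pair_mutation_attempts=60,
        n_snps=80,
        snp_depth=100,
        n_taxa=12,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    return generate_community(small_config)
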