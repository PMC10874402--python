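"""Shared fixtures: a small synthetic genome, gene annotation, and target
design reused across test modules (generated once per session)."""

import pytest

from taslrs import simulate as sim
from taslrs import targets as targets_mod

SESSION_SEED = 1


@pytest.fixture(scope="session")
def genome():
    return sim.make_genome(SESSION_SEED, lengths={"chr1": 200_000, "chr2": 120_000})


@pytest.fixture(scope="session")
def gene_fixture(genome):
    genes, gtf_text, manifest = sim.make_gene_annotation(SESSION_SEED, genome, n_genes=8)
    return genes, gtf_text, manifest


@pytest.fixture(scope="session")
def genes(gene_fixture):
    return gene_fixture[0]


@pytest.fixture(scope="session")
def target_design(genes, genome):
    return targets_mod.build_target_regions(genes, margin=10_000, chrom_sizes=genome.sizes)
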