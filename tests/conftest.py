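from __future__ import annotations

import pytest

from pylogs.genome import RecombinationMap, SnpRecord
from pylogs.ranking import rank_candidate_genes
from pylogs.simulate import SimulationConfig, simulate_cnv_regions, simulate_gene_sets, simulate_genome


@pytest.fixture
def tiny_map() -> RecombinationMap:
    """One chromosome, six SNPs at known bp/cM positions."""
    return RecombinationMap(
        [
            SnpRecord("s1", "chr1", 100, 0.0),
            SnpRecord("s2", "chr1", 1_000, 2.0),
            SnpRecord("s3", "chr1", 5_000, 7.5),
            SnpRecord("s4", "chr1", 9_000, 10.0),
            SnpRecord("s5", "chr1", 15_000, 14.0),
            SnpRecord("s6", "chr1", 30_000, 20.0),
        ]
    )


SMALL_CONFIG = dict(
    n_chromosomes=2,
    chrom_length_bp=20_000_000,
    n_snps_per_chrom=800,
    n_genes_per_chrom=150,
    gene_length_bp=(10_000, 60_000),
    chrom_span_cm=80.0,
    n_markers=4,
    n_gene_sets=20,
    set_size_range=(10, 30),
    n_cnv_regions=25,
    seed=11,
)


@pytest.fixture(scope="session")
def small_world():
    """A small simulated study: genome, sets, CNVs, and the ranked list."""
    cfg = SimulationConfig(**SMALL_CONFIG)
    genome = simulate_genome(cfg)
    sets, planted = simulate_gene_sets(genome, cfg)
    regions, cnv_truth = simulate_cnv_regions(genome, cfg)
    ranked = rank_candidate_genes(genome.mapped_genes, genome.markers)
    return {
        "config": cfg,
        "genome": genome,
        "sets": sets,
        "planted": planted,
        "regions": regions,
        "cnv_truth": cnv_truth,
        "ranked": ranked,
    }
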