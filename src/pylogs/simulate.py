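"""Seeded synthetic genomes, maps, markers, gene sets, and CNV regions.

The generator produces inputs with the statistical structure the
linkage-ordering method assumes, so every stage is testable without
external downloads:

* a monotone recombination map per chromosome (cumulative cM built from
  exponential increments, so monotonicity holds by construction);
* non-overlapping genes, a configurable fraction guaranteed to contain
  at least one map SNP (genes without SNPs cannot be placed in cM and
  drop out of the analysis);
* linkage markers with LOD scores above the classical significance
  threshold of 3;
* gene-set collections containing one *planted* set whose members
  concentrate within a small genetic halfwidth of the markers — spread
  across different markers, emulating a pathway in which each affected
  family's peak captures a different member — among exchangeable null
  sets;
* CNV regions built around a designated gene subset, wholly containing
  a configurable fraction of it, each labeled gain or loss.

Every operation is deterministic given the config seed; the truth
records (planted membership, contained genes, dosages) serve as oracles
for downstream tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pylogs.cnv import CnvRegion
from pylogs.enrichment import GeneSet
from pylogs.genome import (
    GeneRecord,
    MarkerLocus,
    RecombinationMap,
    SnpRecord,
    gene_genetic_position,
    locate_marker,
)

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "PlantedTruth",
    "CnvTruth",
    "simulate_genome",
    "simulate_gene_sets",
    "simulate_cnv_regions",
]

# distinct RNG stream tags so each operation is independently reproducible
_GENOME_STREAM = 1
_SETS_STREAM = 2
_CNV_STREAM = 3


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults emulate a genome-wide linkage follow-up: 6905 genes (the
    size of a typical within-window gene universe) spread over five
    ~100 cM chromosomes, 29 linkage loci with LOD in (3, 6], and a
    191-set collection in which one planted pathway has 90% of its
    members within 2 cM of some peak.
    """

    n_chromosomes: int = 5
    chrom_length_bp: int = 150_000_000
    n_snps_per_chrom: int = 15_000
    n_genes_per_chrom: int = 1381
    gene_length_bp: tuple[int, int] = (20_000, 100_000)
    gene_snp_fraction: float = 1.0
    chrom_span_cm: float = 100.0
    n_markers: int = 29
    marker_span_bp: tuple[int, int] = (500_000, 3_000_000)
    lod_range: tuple[float, float] = (3.0, 6.0)
    n_gene_sets: int = 191
    set_size_range: tuple[int, int] = (50, 150)
    planted_set_fraction_near_marker: float = 0.9
    planted_halfwidth_cm: float = 2.0
    n_cnv_regions: int = 300
    cnv_gene_containment_fraction: float = 1.0
    gain_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length_bp", "n_genes_per_chrom", "n_gene_sets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_snps_per_chrom", "n_markers", "n_cnv_regions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "gene_snp_fraction",
            "planted_set_fraction_near_marker",
            "cnv_gene_containment_fraction",
            "gain_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("gene_length_bp", "marker_span_bp", "lod_range", "set_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
        if self.lod_range[0] <= 0:
            raise ValueError("lod_range low bound must be > 0")
        if self.planted_halfwidth_cm <= 0:
            raise ValueError("planted_halfwidth_cm must be positive")
        if self.chrom_span_cm <= 0:
            raise ValueError("chrom_span_cm must be positive")


@dataclass
class SyntheticGenome:
    """A simulated genome: map, cM-annotated genes, located markers."""

    config: SimulationConfig
    rmap: RecombinationMap | None
    genes: list[GeneRecord]
    markers: list[MarkerLocus]

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.config.n_chromosomes)]

    @property
    def mapped_genes(self) -> list[GeneRecord]:
        """Genes with a defined genetic position (the analysis universe)."""
        return [g for g in self.genes if g.cm is not None]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for the planted gene set."""

    set_name: str
    members: frozenset[str]
    near_members: frozenset[str]
    marker_of_member: dict[str, str] = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class CnvTruth:
    """Ground truth for the simulated CNV regions."""

    designated: tuple[str, ...]
    contained: frozenset[str]
    dosage: dict[str, str] = field(default_factory=dict, compare=False)


def _place_genes(rng: np.random.Generator, cfg: SimulationConfig, chrom: str) -> list[GeneRecord]:
    n = cfg.n_genes_per_chrom
    lo, hi = cfg.gene_length_bp
    lengths = rng.integers(lo, hi + 1, size=n)
    total = int(lengths.sum())
    free = cfg.chrom_length_bp - total
    if free < n + 1:
        raise ValueError(
            f"infeasible packing: {n} genes totalling {total} bp do not fit in "
            f"{cfg.chrom_length_bp} bp on {chrom}"
        )
    w = rng.random(n + 1)
    gaps = np.floor(w / w.sum() * free).astype(np.int64)
    starts = np.cumsum(gaps[:-1]) + np.concatenate(([0], np.cumsum(lengths[:-1])))
    return [
        GeneRecord(f"{chrom}_g{j + 1:04d}", chrom, int(s), int(s + L))
        for j, (s, L) in enumerate(zip(starts, lengths))
    ]


def _place_snps(
    rng: np.random.Generator, cfg: SimulationConfig, chrom: str, genes: list[GeneRecord]
) -> list[SnpRecord]:
    n_snps = cfg.n_snps_per_chrom
    if n_snps == 0:
        return []
    n_guaranteed = int(round(cfg.gene_snp_fraction * len(genes)))
    if n_guaranteed > n_snps:
        raise ValueError(
            f"{chrom}: cannot guarantee a SNP in {n_guaranteed} genes with only {n_snps} SNPs"
        )
    pos: list[np.ndarray] = []
    if n_guaranteed:
        idx = rng.choice(len(genes), size=n_guaranteed, replace=False)
        pos.append(
            np.asarray([rng.integers(genes[i].start_bp, genes[i].end_bp) for i in idx], dtype=np.int64)
        )
    n_extra = n_snps - n_guaranteed
    if n_extra:
        pos.append(rng.integers(0, cfg.chrom_length_bp, size=n_extra, dtype=np.int64))
    bp = np.unique(np.concatenate(pos))
    incr = rng.exponential(scale=cfg.chrom_span_cm / bp.size, size=bp.size)
    cm = np.cumsum(incr)
    return [
        SnpRecord(f"{chrom}_snp{j + 1}", chrom, int(b), float(c))
        for j, (b, c) in enumerate(zip(bp, cm))
    ]


def simulate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Simulate map, genes, and located linkage markers.

    SNP bp positions are drawn uniformly then sorted; cumulative cM is
    built from non-negative exponential increments, so the map is
    monotone by construction.  Genes are non-overlapping; markers are
    assigned round-robin across chromosomes, centered in the middle 40%
    of the chromosome, with LOD drawn uniformly from ``lod_range``.
    Same seed implies identical output.
    """
    rng = np.random.default_rng([_GENOME_STREAM, config.seed])
    snps: list[SnpRecord] = []
    genes: list[GeneRecord] = []
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    for chrom in chrom_names:
        chrom_genes = _place_genes(rng, config, chrom)
        snps.extend(_place_snps(rng, config, chrom, chrom_genes))
        genes.extend(chrom_genes)

    rmap = RecombinationMap(snps) if snps else None
    if rmap is not None:
        genes = [
            GeneRecord(
                g.gene_id,
                g.chrom,
                g.start_bp,
                g.end_bp,
                gene_genetic_position(g, rmap) if g.chrom in rmap else None,
            )
            for g in genes
        ]

    markers: list[MarkerLocus] = []
    for i in range(config.n_markers):
        chrom = chrom_names[i % config.n_chromosomes]
        span = int(rng.integers(config.marker_span_bp[0], config.marker_span_bp[1] + 1))
        center = int(rng.uniform(0.3, 0.7) * config.chrom_length_bp)
        start = max(0, center - span // 2)
        end = min(config.chrom_length_bp, start + span)
        lod = float(rng.uniform(*config.lod_range))
        if rmap is None or chrom not in rmap:
            continue  # nothing to locate the marker against
        markers.append(locate_marker(f"locus{i + 1:02d}_{chrom}", chrom, start, end, lod, rmap))

    return SyntheticGenome(config=config, rmap=rmap, genes=genes, markers=markers)


def simulate_gene_sets(
    genome: SyntheticGenome, config: SimulationConfig | None = None
) -> tuple[list[GeneSet], PlantedTruth]:
    """Null gene sets plus one planted set concentrated near markers.

    ``n_gene_sets − 1`` null sets are sampled uniformly from the gene
    universe (genes with a cM position).  The planted set draws a
    ``planted_set_fraction_near_marker`` of its members from genes
    within ``planted_halfwidth_cm`` of a marker, cycling across markers
    so the signal is spread over different peaks; the remainder is
    uniform.
    """
    config = config or genome.config
    rng = np.random.default_rng([_SETS_STREAM, config.seed])
    universe = [g for g in genome.mapped_genes]
    ids = np.asarray([g.gene_id for g in universe], dtype=object)
    if ids.size == 0:
        raise ValueError("gene universe is empty: no gene has a genetic position")

    lo, hi = config.set_size_range
    hi = min(hi, ids.size - 1)
    if lo > hi:
        raise ValueError("set_size_range infeasible for this gene universe")
    sizes = rng.integers(lo, hi + 1, size=config.n_gene_sets)

    sets: list[GeneSet] = []
    for j in range(config.n_gene_sets - 1):
        members = rng.choice(ids, size=int(sizes[j]), replace=False)
        sets.append(GeneSet.from_iterable(f"set{j + 1:03d}", members.tolist()))

    size = int(sizes[-1])
    n_near = int(round(config.planted_set_fraction_near_marker * size))
    # candidate pools: genes within the halfwidth of each marker
    pools: list[tuple[str, list[str]]] = []
    for m in genome.markers:
        near = [
            g.gene_id
            for g in universe
            if g.chrom == m.chrom and abs(g.cm - m.cm) <= config.planted_halfwidth_cm
        ]
        if near:
            rng.shuffle(near)
            pools.append((m.label, near))
    chosen: dict[str, str] = {}
    pool_idx = 0
    while len(chosen) < n_near and pools:
        label, near = pools[pool_idx % len(pools)]
        while near and near[-1] in chosen:
            near.pop()
        if not near:
            pools.pop(pool_idx % len(pools))
            continue
        chosen[near.pop()] = label
        pool_idx += 1
    if len(chosen) < n_near:
        raise ValueError(
            f"only {len(chosen)} distinct genes lie within {config.planted_halfwidth_cm} cM "
            f"of a marker; cannot plant {n_near} near members"
        )
    far_pool = np.asarray([g for g in ids if g not in chosen], dtype=object)
    far = rng.choice(far_pool, size=size - n_near, replace=False).tolist()
    members = frozenset(chosen) | frozenset(far)
    sets.append(GeneSet("planted", members))
    truth = PlantedTruth(
        set_name="planted",
        members=members,
        near_members=frozenset(chosen),
        marker_of_member=dict(chosen),
    )
    return sets, truth


def simulate_cnv_regions(
    genome: SyntheticGenome, config: SimulationConfig | None = None
) -> tuple[list[CnvRegion], CnvTruth]:
    """CNV regions wholly containing a fraction of a designated gene subset.

    One region is built around each of ``n_cnv_regions`` designated
    genes.  For the contained fraction, the region extends from within
    the gap to the previous gene to within the gap to the next gene, so
    it contains exactly its designated gene; for the remainder, the
    region starts strictly inside the gene (overlap without
    containment).  Dosage is gain with probability
    ``gain_probability``, else loss.
    """
    config = config or genome.config
    rng = np.random.default_rng([_CNV_STREAM, config.seed])
    if config.n_cnv_regions == 0:
        return [], CnvTruth(designated=(), contained=frozenset(), dosage={})
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genome.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.start_bp)
    neighbor_bounds: dict[str, tuple[int, int]] = {}
    for gs in by_chrom.values():
        for i, g in enumerate(gs):
            left = gs[i - 1].end_bp if i > 0 else 0
            right = gs[i + 1].start_bp if i + 1 < len(gs) else genome.config.chrom_length_bp
            neighbor_bounds[g.gene_id] = (left, right)

    all_genes = list(genome.genes)
    if config.n_cnv_regions > len(all_genes):
        raise ValueError("n_cnv_regions exceeds the number of genes")
    designated_idx = rng.choice(len(all_genes), size=config.n_cnv_regions, replace=False)
    designated = [all_genes[i] for i in designated_idx]
    n_contained = int(round(config.cnv_gene_containment_fraction * len(designated)))

    regions: list[CnvRegion] = []
    dosage_of: dict[str, str] = {}
    contained_ids: list[str] = []
    for i, g in enumerate(designated):
        left, right = neighbor_bounds[g.gene_id]
        dosage = "gain" if rng.random() < config.gain_probability else "loss"
        if i < n_contained:
            start = int(rng.integers(left, g.start_bp + 1))
            end = int(rng.integers(g.end_bp, right + 1))
            contained_ids.append(g.gene_id)
            dosage_of[g.gene_id] = dosage
        else:
            start = int(rng.integers(g.start_bp + 1, g.end_bp))
            end = int(rng.integers(g.end_bp, right + 1))
        regions.append(CnvRegion(g.chrom, start, end, dosage=dosage, region_id=f"cnv{i + 1:03d}"))

    truth = CnvTruth(
        designated=tuple(g.gene_id for g in designated),
        contained=frozenset(contained_ids),
        dosage=dosage_of,
    )
    return regions, truth
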