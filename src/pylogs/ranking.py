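"""Genome-wide gene ranking by LOD-adjusted genetic distance to linkage peaks.

Each gene with a defined cM position is compared against every linkage
marker on its chromosome.  A marker is a candidate only if the raw
absolute genetic distance |gene cM − marker cM| lies within the linkage
window (default 50 cM, the practical limit of detectable linkage,
inclusive).  The gene's score is the minimum over candidate markers of
the LOD-adjusted distance (raw distance divided by the marker's LOD
score; division disabled with ``use_lod=False``).  Genes are then ranked
ascending by score, so rank 1 is the gene the linkage evidence points at
most strongly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from pylogs.genome import GeneRecord, MarkerLocus

logger = logging.getLogger(__name__)

__all__ = ["RankedGene", "RankedGeneList", "RankingConfig", "gene_scores", "rank_genes", "rank_candidate_genes"]


@dataclass(frozen=True)
class RankedGene:
    """A gene's distance-to-peak score and (after ranking) its rank.

    ``raw_cm`` is the unadjusted |gene cM − marker cM| of the marker
    achieving the minimum adjusted score.
    """

    gene_id: str
    raw_cm: float
    score: float
    rank: int | None = None


@dataclass
class RankingConfig:
    """Window size, LOD usage, and optional gene-subset restriction.

    window_cm
        Linkage window in centimorgans; a gene is retained only if some
        same-chromosome marker lies within this raw distance
        (inclusive).  Default 50 cM.  Values above 50 are permitted but
        flagged with a warning (beyond the practical linkage limit).
    use_lod
        Divide raw distance by the marker LOD score before taking the
        minimum over markers (default True).
    gene_subset
        Optional gene-id whitelist applied before scoring, so ranks are
        contiguous within the subset (e.g. restricting to genes found in
        CNV regions).
    """

    window_cm: float = 50.0
    use_lod: bool = True
    gene_subset: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.window_cm <= 0:
            raise ValueError(f"window_cm must be positive, got {self.window_cm}")
        if self.window_cm > 50.0:
            logger.warning("window_cm=%.3g exceeds 50 cM, beyond the usual linkage window", self.window_cm)


class RankedGeneList:
    """The ranked gene list: RankedGene records ordered by rank 1..N."""

    def __init__(self, genes: Sequence[RankedGene]) -> None:
        self._genes = list(genes)
        self._pos = {g.gene_id: i for i, g in enumerate(self._genes)}
        if len(self._pos) != len(self._genes):
            raise ValueError("duplicate gene ids in ranked list")

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[RankedGene]:
        return iter(self._genes)

    def __getitem__(self, i: int) -> RankedGene:
        return self._genes[i]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._pos

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self._genes]

    def position(self, gene_id: str) -> int:
        """0-based position (= rank − 1) of a gene in the list."""
        return self._pos[gene_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self._genes],
                "raw_cm": [g.raw_cm for g in self._genes],
                "score": [g.score for g in self._genes],
                "rank": [g.rank for g in self._genes],
            }
        )


def gene_scores(
    genes: Sequence[GeneRecord],
    markers: Sequence[MarkerLocus],
    config: RankingConfig | None = None,
) -> list[RankedGene]:
    """Unranked LOD-adjusted distance scores for every retainable gene.

    Genes must carry a cM position.  For each gene, candidate markers
    are the same-chromosome markers with raw distance <= window; the
    score is the minimum LOD-adjusted distance over candidates; genes
    with no in-window marker are dropped.  Raises if nothing survives.
    """
    config = config or RankingConfig()
    if config.gene_subset is not None:
        keep = set(config.gene_subset)
        genes = [g for g in genes if g.gene_id in keep]
    for g in genes:
        if g.cm is None:
            raise ValueError(f"gene {g.gene_id} has no genetic position; exclude it before scoring")

    gene_chroms = {g.chrom for g in genes}
    by_chrom_markers: dict[str, list[MarkerLocus]] = {}
    for m in markers:
        if m.chrom not in gene_chroms:
            logger.warning("marker %s on chromosome %s has no genes in the universe; skipped", m.label, m.chrom)
            continue
        by_chrom_markers.setdefault(m.chrom, []).append(m)

    out: list[RankedGene] = []
    by_chrom_genes: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom_genes.setdefault(g.chrom, []).append(g)

    for chrom, chrom_genes in by_chrom_genes.items():
        ms = by_chrom_markers.get(chrom)
        if not ms:
            continue
        g_cm = np.asarray([g.cm for g in chrom_genes], dtype=np.float64)
        m_cm = np.asarray([m.cm for m in ms], dtype=np.float64)
        m_lod = np.asarray([m.lod for m in ms], dtype=np.float64)
        raw = np.abs(g_cm[:, None] - m_cm[None, :])  # genes x markers
        in_window = raw <= config.window_cm
        adjusted = raw / m_lod[None, :] if config.use_lod else raw.copy()
        adjusted[~in_window] = np.inf
        best = np.argmin(adjusted, axis=1)
        best_adj = adjusted[np.arange(len(chrom_genes)), best]
        best_raw = raw[np.arange(len(chrom_genes)), best]
        for g, a, r, ok in zip(chrom_genes, best_adj, best_raw, np.isfinite(best_adj)):
            if ok:
                out.append(RankedGene(g.gene_id, float(r), float(a)))

    if not out:
        raise ValueError(
            f"no gene lies within {config.window_cm} cM of any marker; consider a larger window"
        )
    return out


def rank_genes(scores: Sequence[RankedGene]) -> RankedGeneList:
    """Ascending sort by score; ties by (raw_cm, gene_id); ranks 1..N."""
    if not scores:
        raise ValueError("cannot rank an empty score list")
    ordered = sorted(scores, key=lambda g: (g.score, g.raw_cm, g.gene_id))
    return RankedGeneList(
        [RankedGene(g.gene_id, g.raw_cm, g.score, rank=i + 1) for i, g in enumerate(ordered)]
    )


def rank_candidate_genes(
    genes: Sequence[GeneRecord],
    markers: Sequence[MarkerLocus],
    config: RankingConfig | None = None,
) -> RankedGeneList:
    """Convenience: score then rank in one call."""
    return rank_genes(gene_scores(genes, markers, config))
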