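"""Physical (bp) and genetic (cM) coordinate systems.

A recombination map is an ordered table of SNP landmarks per chromosome,
each carrying a base-pair position and a cumulative genetic position in
centimorgans.  Genes and linkage markers receive genetic positions by
SNP lookup only — no interpolation between landmarks — mirroring how
HapMap-style maps are used in linkage follow-up work:

* a gene's cM position is the mean of the cM of the left-most and
  right-most map SNPs inside the gene body (a single inside SNP stands
  alone; a gene containing no SNP has no genetic position and is
  excluded downstream);
* a marker's cM position is the cM of the map SNP nearest (in bp) to the
  midpoint of the marker's reported bp range.

Genes and CNV regions use the BED convention (0-based, half-open).
Marker ranges printed in literature tables are 1-based inclusive and are
converted on input by the readers in :mod:`pylogs.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SnpRecord",
    "RecombinationMap",
    "GeneRecord",
    "MarkerLocus",
    "gene_genetic_position",
    "marker_genetic_position",
    "locate_marker",
]


@dataclass(frozen=True)
class SnpRecord:
    """A SNP landmark on the recombination map."""

    snp_id: str
    chrom: str
    bp: int
    cm: float

    def __post_init__(self) -> None:
        if self.bp < 0:
            raise ValueError(f"SNP {self.snp_id}: bp must be >= 0, got {self.bp}")
        if self.cm < 0:
            raise ValueError(f"SNP {self.snp_id}: cM must be >= 0, got {self.cm}")


class RecombinationMap:
    """Per-chromosome ordered SNP landmarks bridging bp and cM.

    Parameters
    ----------
    records
        SNP records in any order.  Within each chromosome, bp positions
        must be unique and cumulative cM must be non-decreasing when
        sorted by bp.
    """

    def __init__(self, records: Iterable[SnpRecord]) -> None:
        by_chrom: dict[str, list[SnpRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        if not by_chrom:
            raise ValueError("recombination map has no SNP records")
        self._bp: dict[str, np.ndarray] = {}
        self._cm: dict[str, np.ndarray] = {}
        self._ids: dict[str, list[str]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r.bp)
            bp = np.asarray([r.bp for r in recs], dtype=np.int64)
            cm = np.asarray([r.cm for r in recs], dtype=np.float64)
            if np.any(np.diff(bp) == 0):
                dup = int(bp[np.flatnonzero(np.diff(bp) == 0)[0]])
                raise ValueError(f"chromosome {chrom}: duplicate SNP bp position {dup}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom}: cumulative cM decreases along bp order")
            self._bp[chrom] = bp
            self._cm[chrom] = cm
            self._ids[chrom] = [r.snp_id for r in recs]

    @property
    def chroms(self) -> list[str]:
        return list(self._bp)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._bp

    def n_snps(self, chrom: str) -> int:
        self._require(chrom)
        return int(self._bp[chrom].size)

    def positions(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """bp and cM arrays (bp-sorted) for one chromosome."""
        self._require(chrom)
        return self._bp[chrom], self._cm[chrom]

    def records(self, chrom: str) -> list[SnpRecord]:
        self._require(chrom)
        return [
            SnpRecord(sid, chrom, int(b), float(c))
            for sid, b, c in zip(self._ids[chrom], self._bp[chrom], self._cm[chrom])
        ]

    def _require(self, chrom: str) -> None:
        if chrom not in self._bp:
            raise KeyError(f"chromosome {chrom!r} not present in recombination map")


@dataclass
class GeneRecord:
    """A gene's physical interval (0-based half-open) and optional cM position."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    cm: float | None = None

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError(
                f"gene {self.gene_id}: start_bp must be < end_bp "
                f"(got [{self.start_bp}, {self.end_bp}))"
            )


@dataclass(frozen=True)
class MarkerLocus:
    """A linkage peak: bp range, LOD score, and derived cM position.

    ``start_bp``/``end_bp`` are stored 0-based half-open.  When several
    LOD scores are reported for one locus, callers supply the lower one
    (the conservative choice).
    """

    label: str
    chrom: str
    start_bp: int
    end_bp: int
    lod: float
    cm: float

    def __post_init__(self) -> None:
        if self.lod <= 0:
            raise ValueError(f"marker {self.label}: LOD must be > 0, got {self.lod}")
        if self.start_bp > self.end_bp:
            raise ValueError(f"marker {self.label}: start_bp > end_bp")


def gene_genetic_position(gene: GeneRecord, rmap: RecombinationMap) -> float | None:
    """cM position of a gene, or ``None`` if no map SNP lies inside it.

    With two or more map SNPs inside ``[start_bp, end_bp)``, the
    position is the mean of the cM of the SNP with smallest bp and the
    SNP with largest bp inside the interval; with exactly one inside
    SNP, that SNP's cM.  Genes with no inside SNP have no genetic
    position and are excluded from ranking.
    """
    bp, cm = rmap.positions(gene.chrom)
    lo = int(np.searchsorted(bp, gene.start_bp, side="left"))
    hi = int(np.searchsorted(bp, gene.end_bp, side="left"))
    n_inside = hi - lo
    if n_inside == 0:
        return None
    if n_inside == 1:
        return float(cm[lo])
    return float((cm[lo] + cm[hi - 1]) / 2.0)


def marker_genetic_position(chrom: str, start_bp: int, end_bp: int, rmap: RecombinationMap) -> float:
    """cM of the map SNP nearest (in bp) to the midpoint of a marker range.

    The midpoint uses integer floor division; a bp tie between two SNPs
    is broken toward the lower-bp SNP.
    """
    if start_bp > end_bp:
        raise ValueError(f"marker range start_bp {start_bp} > end_bp {end_bp}")
    bp, cm = rmap.positions(chrom)
    mid = (start_bp + end_bp) // 2
    idx = int(np.searchsorted(bp, mid, side="left"))
    candidates = [i for i in (idx - 1, idx) if 0 <= i < bp.size]
    # distance tie resolves to the lower-bp candidate, which comes first
    best = min(candidates, key=lambda i: (abs(int(bp[i]) - mid), int(bp[i])))
    return float(cm[best])


def locate_marker(
    label: str,
    chrom: str,
    start_bp: int,
    end_bp: int,
    lod: float,
    rmap: RecombinationMap,
) -> MarkerLocus:
    """Build a :class:`MarkerLocus` with its cM derived from the map."""
    cm = marker_genetic_position(chrom, start_bp, end_bp, rmap)
    return MarkerLocus(label=label, chrom=chrom, start_bp=start_bp, end_bp=end_bp, lod=lod, cm=cm)


def assign_gene_positions(genes: Sequence[GeneRecord], rmap: RecombinationMap) -> list[GeneRecord]:
    """Return copies of ``genes`` with cM filled in where defined.

    Genes on chromosomes absent from the map keep ``cm=None`` (there are
    no landmarks to place them against).
    """
    out: list[GeneRecord] = []
    for g in genes:
        cm = gene_genetic_position(g, rmap) if g.chrom in rmap else None
        out.append(GeneRecord(g.gene_id, g.chrom, g.start_bp, g.end_bp, cm))
    return out
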