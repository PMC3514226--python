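"""Structural-variation arm: CNV-contained genes and EASE category enrichment.

Genes qualifying for the CNV gene list are those *wholly contained* in
some copy-number-variant region (overlap is not enough); containment is
evaluated on half-open intervals, so equal boundaries count as
contained.  Annotation categories are then scored with the EASE
statistic — a conservative variant of the one-tailed Fisher exact test
that removes one gene from the category overlap before computing the
hypergeometric upper-tail probability — with Bonferroni correction over
the categories actually tested (those with at least one hit).  Top
categories can be exported as new gene sets and fed back into the
ranking analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import hypergeom

__all__ = [
    "CnvRegion",
    "Containment",
    "CategoryEnrichment",
    "genes_wholly_within",
    "ease_score",
    "enrich_categories",
    "export_icnv_sets",
    "annotate_dosage",
]

from pylogs.enrichment import GeneSet
from pylogs.genome import GeneRecord

DOSAGES = ("gain", "loss")


@dataclass(frozen=True)
class CnvRegion:
    """A structural-variation interval (0-based half-open), optional dosage."""

    chrom: str
    start_bp: int
    end_bp: int
    dosage: str | None = None
    region_id: str | None = None

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError(f"CNV region: start_bp must be < end_bp, got [{self.start_bp}, {self.end_bp})")
        if self.dosage is not None and self.dosage not in DOSAGES:
            raise ValueError(f"CNV dosage must be one of {DOSAGES} or None, got {self.dosage!r}")


@dataclass(frozen=True)
class Containment:
    """One gene wholly inside one witness region."""

    gene_id: str
    region: CnvRegion
    dosage: str | None


@dataclass(frozen=True)
class CategoryEnrichment:
    category: str
    hits_in_list: int
    list_size: int
    hits_in_background: int
    background_size: int
    ease_p: float
    bonferroni_p: float
    rank: int


def genes_wholly_within(
    genes: Sequence[GeneRecord],
    regions: Sequence[CnvRegion],
    all_witnesses: bool = False,
) -> list[Containment]:
    """Genes completely residing inside a CNV region.

    A gene qualifies iff some same-chromosome region satisfies
    ``region.start_bp <= gene.start_bp and gene.end_bp <= region.end_bp``.
    By default each qualifying gene reports one witness region — the
    first by (start, end) coordinate — and its dosage; with
    ``all_witnesses=True`` every containing region is reported (needed
    to detect conflicting dosages).  Output follows gene input order.
    """
    by_chrom: dict[str, list[CnvRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for rs in by_chrom.values():
        rs.sort(key=lambda r: (r.start_bp, r.end_bp))

    out: list[Containment] = []
    for g in genes:
        witnesses = [
            r
            for r in by_chrom.get(g.chrom, ())
            if r.start_bp <= g.start_bp and g.end_bp <= r.end_bp
        ]
        if not witnesses:
            continue
        if all_witnesses:
            out.extend(Containment(g.gene_id, r, r.dosage) for r in witnesses)
        else:
            r = witnesses[0]
            out.append(Containment(g.gene_id, r, r.dosage))
    return out


def ease_score(k: int, n: int, K: int, N: int, jackknife: bool = True) -> float:
    """EASE p-value for a 2x2 overlap table.

    k hits in a list of size n, against K category members in a
    background of size N.  The jackknife replaces k by max(k − 1, 0)
    before taking the hypergeometric upper tail P(X >= k'), which makes
    single-gene overlaps unscoreable (p = 1) and every p conservative
    relative to the plain one-tailed Fisher exact test.  Set
    ``jackknife=False`` for the plain Fisher upper tail.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"inconsistent table margins: k={k}, n={n}, K={K}, N={N}"
        )
    kk = max(k - 1, 0) if jackknife else k
    # P(X >= kk) for X ~ Hypergeom(N, K, n)
    return float(hypergeom.sf(kk - 1, N, K, n))


def enrich_categories(
    gene_list: Sequence[str],
    annotation: Mapping[str, Sequence[str]],
    background: Sequence[str],
    jackknife: bool = True,
    top: int | None = None,
) -> list[CategoryEnrichment]:
    """EASE-score every annotation category hit by the gene list.

    Categories with zero hits are not tested and do not count toward
    the Bonferroni denominator.  Output ascends by ease_p (ties by
    category name); ``top`` truncates for presentation.
    """
    genes = set(gene_list)
    bg = set(background)
    if not genes:
        raise ValueError("gene_list is empty")
    if not genes <= bg:
        missing = sorted(genes - bg)[:5]
        raise ValueError(f"gene_list is not a subset of the background (e.g. {missing})")
    n = len(genes)
    N = len(bg)

    tested: list[tuple[str, int, int, float]] = []
    for category, members in annotation.items():
        cat_bg = set(members) & bg
        k = len(cat_bg & genes)
        if k == 0:
            continue
        K = len(cat_bg)
        tested.append((category, k, K, ease_score(k, n, K, N, jackknife=jackknife)))
    n_tests = len(tested)

    tested.sort(key=lambda t: (t[3], t[0]))
    results = [
        CategoryEnrichment(
            category=category,
            hits_in_list=k,
            list_size=n,
            hits_in_background=K,
            background_size=N,
            ease_p=p,
            bonferroni_p=min(1.0, p * n_tests),
            rank=i + 1,
        )
        for i, (category, k, K, p) in enumerate(tested)
    ]
    return results[:top] if top is not None else results


def export_icnv_sets(
    enrichments: Sequence[CategoryEnrichment],
    selected_ranks: Sequence[int],
    annotation: Mapping[str, Sequence[str]],
    background: Sequence[str] | None = None,
) -> list[GeneSet]:
    """Turn selected enriched categories into gene sets.

    Each selected category becomes a set named after it, containing the
    category's background member genes (all annotation members, or
    their intersection with ``background`` when given).  The result is
    appendable to an existing GMT collection.
    """
    wanted = set(selected_ranks)
    missing = wanted - {e.rank for e in enrichments}
    if missing:
        raise ValueError(f"selected ranks not present in enrichment results: {sorted(missing)}")
    bg = set(background) if background is not None else None
    out: list[GeneSet] = []
    for e in sorted(enrichments, key=lambda e: e.rank):
        if e.rank not in wanted:
            continue
        members = set(annotation[e.category])
        if bg is not None:
            members &= bg
        out.append(GeneSet.from_iterable(e.category, members))
    return out


def annotate_dosage(
    set_members: Sequence[str], containment: Sequence[Containment]
) -> dict[str, str]:
    """Gene → copy-number dosage label from containment records.

    ``gain``/``loss`` when every witness agrees; ``ambiguous`` on
    conflicting dosages; ``unknown`` when contained only in unlabeled
    regions; ``absent`` for members with no containment record.  Pass
    ``genes_wholly_within(..., all_witnesses=True)`` output to detect
    conflicts across multiple witness regions.
    """
    seen: dict[str, set[str | None]] = {}
    for c in containment:
        seen.setdefault(c.gene_id, set()).add(c.dosage)
    out: dict[str, str] = {}
    for g in set_members:
        dosages = seen.get(g)
        if dosages is None:
            out[g] = "absent"
            continue
        labeled = {d for d in dosages if d is not None}
        if not labeled:
            out[g] = "unknown"
        elif len(labeled) == 1:
            out[g] = next(iter(labeled))
        else:
            out[g] = "ambiguous"
    return out
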