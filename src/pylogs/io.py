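"""Readers and writers for the standard input/output formats.

Formats handled:

* recombination map — HapMap-style TSV per chromosome with a header;
  columns ``snp_id``, ``position_bp``, ``cumulative_cM`` are consumed
  (a ``rate_cM_per_Mb`` column may be present and is ignored).  A map
  may be a single file carrying a ``chrom`` column, or a directory of
  per-chromosome files named ``genetic_map_<chrom>.tsv``;
* genes — BED4 (chrom, start, end, gene_id), 0-based half-open;
* linkage markers — TSV (label, chrom, start_bp, end_bp, lod) with a
  header; ranges are 1-based inclusive as printed in literature tables
  and are converted to 0-based half-open on input;
* gene sets — GMT (name, description, tab-separated members);
* CNV regions — BED4+1 (chrom, start, end, region_id, dosage) with
  dosage in {gain, loss, .}.

Tabular outputs are TSV preceded by '#'-prefixed provenance header
lines recording the inputs, seed, and parameters of the run.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from pylogs.cnv import CategoryEnrichment, CnvRegion
from pylogs.enrichment import EnrichmentResult, GeneSet
from pylogs.genome import GeneRecord, MarkerLocus, RecombinationMap, SnpRecord, locate_marker
from pylogs.ranking import RankedGeneList

logger = logging.getLogger(__name__)

__all__ = [
    "read_map",
    "write_map",
    "read_genes_bed",
    "write_genes_bed",
    "read_markers",
    "write_markers",
    "locate_markers",
    "read_gmt",
    "write_gmt",
    "read_cnv_bed",
    "write_cnv_bed",
    "write_ranking",
    "read_ranking",
    "write_enrichment",
    "write_categories",
]

_MAP_COLUMNS = ("snp_id", "position_bp", "cumulative_cM")


def _read_map_frame(path: Path, chrom: str | None) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: map file lacks required columns {missing}")
    if chrom is None:
        if "chrom" not in df.columns:
            raise ValueError(f"{path}: single-file map needs a 'chrom' column")
        chroms = df["chrom"].astype(str)
    else:
        chroms = pd.Series([chrom] * len(df))
    return [
        SnpRecord(str(s), c, int(b), float(m))
        for s, c, b, m in zip(df["snp_id"], chroms, df["position_bp"], df["cumulative_cM"])
    ]


def read_map(path: str | os.PathLike) -> RecombinationMap:
    """Read a recombination map from a TSV file or a directory of them."""
    p = Path(path)
    if p.is_dir():
        records: list[SnpRecord] = []
        files = sorted(p.glob("*.tsv"))
        if not files:
            raise FileNotFoundError(f"no .tsv map files found in {p}")
        for f in files:
            chrom = f.stem
            if chrom.startswith("genetic_map_"):
                chrom = chrom[len("genetic_map_"):]
            records.extend(_read_map_frame(f, chrom))
        return RecombinationMap(records)
    return RecombinationMap(_read_map_frame(p, None))


def write_map(rmap: RecombinationMap, out_dir: str | os.PathLike) -> list[Path]:
    """Write one ``genetic_map_<chrom>.tsv`` per chromosome."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for chrom in rmap.chroms:
        bp, cm = rmap.positions(chrom)
        df = pd.DataFrame(
            {"snp_id": [r.snp_id for r in rmap.records(chrom)], "position_bp": bp, "cumulative_cM": cm}
        )
        path = out / f"genetic_map_{chrom}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths.append(path)
    return paths


def read_genes_bed(path: str | os.PathLike) -> list[GeneRecord]:
    """Read BED4 gene annotations; duplicate gene ids are an error."""
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED4 requires 4 columns, got {len(parts)}")
            chrom, start, end, gene_id = parts[:4]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if s >= e:
                raise ValueError(f"{path}:{ln}: start {s} >= end {e}")
            if gene_id in seen:
                raise ValueError(f"{path}:{ln}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneRecord(gene_id, chrom, s, e))
    return genes


def write_genes_bed(genes: Sequence[GeneRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start_bp}\t{g.end_bp}\t{g.gene_id}\n")


def read_markers(path: str | os.PathLike) -> list[tuple[str, str, int, int, float]]:
    """Read linkage markers; 1-based inclusive ranges become half-open.

    Returns raw (label, chrom, start_bp, end_bp, lod) tuples in internal
    coordinates; use :func:`locate_markers` to derive cM positions.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ("label", "chrom", "start_bp", "end_bp", "lod")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: marker file lacks required columns {missing}")
    out = []
    for t in df.itertuples(index=False):
        start, end = int(t.start_bp), int(t.end_bp)
        if start > end:
            raise ValueError(f"{path}: marker {t.label}: start_bp {start} > end_bp {end}")
        out.append((str(t.label), str(t.chrom), start - 1, end, float(t.lod)))
    return out


def write_markers(markers: Sequence[MarkerLocus], path: str | os.PathLike) -> None:
    """Write markers, converting internal half-open back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("label\tchrom\tstart_bp\tend_bp\tlod\n")
        for m in markers:
            fh.write(f"{m.label}\t{m.chrom}\t{m.start_bp + 1}\t{m.end_bp}\t{m.lod:.10g}\n")


def locate_markers(
    raw: Sequence[tuple[str, str, int, int, float]], rmap: RecombinationMap
) -> list[MarkerLocus]:
    return [locate_marker(label, chrom, s, e, lod, rmap) for label, chrom, s, e, lod in raw]


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Read a GMT gene-set collection; duplicate members are collapsed."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT requires name, description, >=1 member")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if len(members) != len(set(members)):
                logger.warning("%s:%d: set %s has duplicate members; deduplicated", path, ln, name)
            if not members:
                raise ValueError(f"{path}:{ln}: set {name!r} has no members")
            sets.append(GeneSet.from_iterable(name, members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | os.PathLike, append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.members)]) + "\n")


_DOSAGE_TOKENS = {"gain": "gain", "loss": "loss", ".": None}


def read_cnv_bed(path: str | os.PathLike) -> list[CnvRegion]:
    """Read BED4+1 CNV regions (chrom, start, end, region_id, dosage)."""
    regions: list[CnvRegion] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: CNV BED requires >=4 columns")
            chrom, start, end, region_id = parts[:4]
            token = parts[4] if len(parts) > 4 else "."
            if token not in _DOSAGE_TOKENS:
                raise ValueError(
                    f"{path}:{ln}: unknown dosage token {token!r}; allowed: "
                    f"{sorted(_DOSAGE_TOKENS)}"
                )
            s, e = int(start), int(end)
            if s >= e:
                raise ValueError(f"{path}:{ln}: start {s} >= end {e}")
            regions.append(CnvRegion(chrom, s, e, dosage=_DOSAGE_TOKENS[token], region_id=region_id))
    return regions


def write_cnv_bed(regions: Sequence[CnvRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            rid = r.region_id or f"cnv{i}"
            fh.write(f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{rid}\t{r.dosage or '.'}\n")


def _provenance_lines(provenance: Mapping[str, object] | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_ranking(
    ranked: RankedGeneList, path: str | os.PathLike, provenance: Mapping[str, object] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("gene_id\traw_cm\tscore\trank\n")
        for g in ranked:
            fh.write(f"{g.gene_id}\t{g.raw_cm:.10g}\t{g.score:.10g}\t{g.rank}\n")


def read_ranking(path: str | os.PathLike) -> RankedGeneList:
    from pylogs.ranking import RankedGene

    df = pd.read_csv(path, sep="\t", comment="#")
    genes = [
        RankedGene(str(t.gene_id), float(t.raw_cm), float(t.score), int(t.rank))
        for t in df.itertuples(index=False)
    ]
    return RankedGeneList(sorted(genes, key=lambda g: g.rank))


def write_enrichment(
    results: Sequence[EnrichmentResult],
    path: str | os.PathLike,
    provenance: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("rank\tset_name\tn_in_list\tV\tp\tp_display\tmode\tn_perm\n")
        for i, r in enumerate(results, start=1):
            fh.write(
                f"{i}\t{r.set_name}\t{r.n_in_list}\t{r.v_score:.10g}\t{r.p_value:.10g}\t"
                f"{r.p_display()}\t{r.mode}\t{r.n_perm}\n"
            )


def write_categories(
    results: Sequence[CategoryEnrichment],
    path: str | os.PathLike,
    provenance: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write(
            "rank\tcategory\thits_in_list\tlist_size\thits_in_background\t"
            "background_size\tease_p\tbonferroni_p\n"
        )
        for r in results:
            fh.write(
                f"{r.rank}\t{r.category}\t{r.hits_in_list}\t{r.list_size}\t"
                f"{r.hits_in_background}\t{r.background_size}\t{r.ease_p:.10g}\t{r.bonferroni_p:.10g}\n"
            )
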