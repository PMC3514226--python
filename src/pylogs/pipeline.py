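"""End-to-end pipeline: CNV categories → new gene sets → ranking → enrichment.

The integration scheme: genes wholly contained in CNV regions are
scored against an annotation with the EASE statistic; the top-ranked
categories are exported as new gene sets, merged with the a priori
collection, and the merged collection is tested against the
LOD-normalized distance ranking with the permutation test.  Outputs
(ranked list, CNV category table, final enrichment table, provenance
JSON) are written only after every stage succeeds, so a failing run
leaves no partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

import pylogs.io as pio
from pylogs import __version__
from pylogs.cnv import enrich_categories, export_icnv_sets, genes_wholly_within
from pylogs.enrichment import GeneSet, permutation_test
from pylogs.genome import assign_gene_positions
from pylogs.ranking import RankingConfig, rank_candidate_genes
from pylogs.simulate import SimulationConfig, simulate_cnv_regions, simulate_gene_sets, simulate_genome

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "simulate_bundle"]


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run."""

    map_path: str
    genes_path: str
    markers_path: str
    sets_path: str
    out_dir: str
    cnv_path: str | None = None
    annotation_path: str | None = None  # defaults to sets_path
    background_path: str | None = None  # defaults to all annotation genes
    subset_path: str | None = None
    window_cm: float = 50.0
    use_lod: bool = True
    n_perm: int = 1000
    seed: int = 0
    mode: str = "top_rank"
    statistic: str = "ks"
    n_export: int = 5

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown pipeline config keys {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("map_path", "genes_path", "markers_path", "sets_path",
                     "cnv_path", "annotation_path", "background_path", "subset_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file or directory: {p}")


@dataclass
class PipelineResult:
    ranked_path: Path
    enrichment_path: Path
    categories_path: Path | None
    icnv_gmt_path: Path | None
    provenance_path: Path


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    p = Path(path)
    if p.is_dir():
        for f in sorted(p.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    else:
        h.update(p.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the result bundle.

    Stages: read inputs → CNV containment and category enrichment →
    export of top categories as gene sets (names prefixed ``iCNV:`` to
    avoid collisions with the a priori collection) → distance ranking →
    permutation enrichment → write outputs with provenance.
    """
    config.validate_paths()

    def stage(name: str, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    rmap = stage("read_map", lambda: pio.read_map(config.map_path))
    genes = stage("read_genes", lambda: pio.read_genes_bed(config.genes_path))
    raw_markers = stage("read_markers", lambda: pio.read_markers(config.markers_path))
    sets = stage("read_sets", lambda: pio.read_gmt(config.sets_path))

    categories = None
    icnv_sets: list[GeneSet] = []
    if config.cnv_path is not None:
        regions = stage("read_cnv", lambda: pio.read_cnv_bed(config.cnv_path))
        annotation_sets = (
            stage("read_annotation", lambda: pio.read_gmt(config.annotation_path))
            if config.annotation_path
            else sets
        )
        annotation = {s.name: sorted(s.members) for s in annotation_sets}
        if config.background_path:
            background = stage(
                "read_background",
                lambda: [ln.strip() for ln in open(config.background_path) if ln.strip()],
            )
        else:
            background = sorted({g for members in annotation.values() for g in members})

        def cnv_stage():
            containment = genes_wholly_within(genes, regions)
            cnv_genes = sorted({c.gene_id for c in containment})
            bg = set(background)
            in_bg = [g for g in cnv_genes if g in bg]
            dropped = len(cnv_genes) - len(in_bg)
            if dropped:
                logger.info("%d CNV-contained genes absent from the background were dropped", dropped)
            if not in_bg:
                raise ValueError("no CNV-contained gene lies in the background universe")
            cats = enrich_categories(in_bg, annotation, background)
            exported = export_icnv_sets(
                cats, selected_ranks=range(1, min(config.n_export, len(cats)) + 1),
                annotation=annotation, background=background,
            )
            return cats, [GeneSet(f"iCNV:{s.name}", s.members) for s in exported]

        categories, icnv_sets = stage("cnv_enrichment", cnv_stage)

    def ranking_stage():
        placed = assign_gene_positions(genes, rmap)
        universe = [g for g in placed if g.cm is not None]
        markers = pio.locate_markers(raw_markers, rmap)
        subset = None
        if config.subset_path:
            subset = [ln.strip() for ln in open(config.subset_path) if ln.strip()]
        rc = RankingConfig(window_cm=config.window_cm, use_lod=config.use_lod, gene_subset=subset)
        return rank_candidate_genes(universe, markers, rc)

    ranked = stage("ranking", ranking_stage)

    merged = sets + icnv_sets
    results = stage(
        "enrichment",
        lambda: permutation_test(
            ranked, merged, n_perm=config.n_perm, seed=config.seed,
            mode=config.mode, statistic=config.statistic,
        ),
    )

    # all stages succeeded: write the bundle
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {
        "tool": f"pylogs {__version__}",
        "seed": config.seed,
        "n_perm": config.n_perm,
        "window_cm": config.window_cm,
        "use_lod": config.use_lod,
        "mode": config.mode,
        "statistic": config.statistic,
    }
    ranked_path = out / "ranked_genes.tsv"
    pio.write_ranking(ranked, ranked_path, provenance=prov)
    enrichment_path = out / "logs_enrichment.tsv"
    pio.write_enrichment(results, enrichment_path, provenance=prov)
    categories_path = icnv_path = None
    if categories is not None:
        categories_path = out / "cnv_categories.tsv"
        pio.write_categories(categories, categories_path, provenance=prov)
        icnv_path = out / "icnv_sets.gmt"
        pio.write_gmt(icnv_sets, icnv_path)
    provenance_path = out / "provenance.json"
    inputs = {
        name: {"path": str(p), "sha256": _sha256(p)}
        for name, p in (
            ("map", config.map_path),
            ("genes", config.genes_path),
            ("markers", config.markers_path),
            ("sets", config.sets_path),
            ("cnv", config.cnv_path),
        )
        if p is not None
    }
    provenance_path.write_text(
        json.dumps({"parameters": prov, "inputs": inputs}, indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(ranked_path, enrichment_path, categories_path, icnv_path, provenance_path)


def simulate_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Any]:
    """Simulate a full input bundle and write it to ``out_dir``.

    Writes per-chromosome map TSVs under ``map/``, ``genes.bed``,
    ``markers.tsv``, ``sets.gmt``, ``cnv.bed``, and ``truth.json``
    recording the planted ground truth for downstream oracles.  Returns
    the truth record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    sets, planted = simulate_gene_sets(genome, config)
    regions, cnv_truth = simulate_cnv_regions(genome, config)

    if genome.rmap is not None:
        pio.write_map(genome.rmap, out / "map")
    pio.write_genes_bed(genome.genes, out / "genes.bed")
    pio.write_markers(genome.markers, out / "markers.tsv")
    pio.write_gmt(sets, out / "sets.gmt")
    pio.write_cnv_bed(regions, out / "cnv.bed")
    truth = {
        "config": dataclasses.asdict(config),
        "planted_set": planted.set_name,
        "planted_members": sorted(planted.members),
        "planted_near_members": sorted(planted.near_members),
        "marker_of_member": dict(sorted(planted.marker_of_member.items())),
        "cnv_designated": list(cnv_truth.designated),
        "cnv_contained": sorted(cnv_truth.contained),
        "cnv_dosage": dict(sorted(cnv_truth.dosage.items())),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth
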