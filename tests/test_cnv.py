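"""CNV containment, the EASE statistic, and category enrichment."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import fisher_exact

from helpers import hypergeom_upper_tail, ranked_from_ids
from pylogs.cnv import (
    CnvRegion,
    annotate_dosage,
    ease_score,
    enrich_categories,
    export_icnv_sets,
    genes_wholly_within,
)
from pylogs.enrichment import filter_set
from pylogs.genome import GeneRecord


def gene(gene_id, start, end, chrom="chr1"):
    return GeneRecord(gene_id, chrom, start, end)


class TestContainment:
    @pytest.mark.parametrize(
        "g_start,g_end,included",
        [
            (100, 200, True),   # strictly inside
            (40, 200, False),   # overlap is not containment
            (50, 250, True),    # equal boundaries count under half-open intervals
            (240, 260, False),  # right overhang
        ],
    )
    def test_whole_containment_rule(self, g_start, g_end, included):
        region = CnvRegion("chr1", 50, 250, dosage="gain")
        hits = genes_wholly_within([gene("g", g_start, g_end)], [region])
        assert bool(hits) == included

    def test_witness_is_first_by_coordinate_and_order_invariant(self):
        regions = [
            CnvRegion("chr1", 80, 400, dosage="loss", region_id="b"),
            CnvRegion("chr1", 50, 300, dosage="gain", region_id="a"),
        ]
        [hit] = genes_wholly_within([gene("g", 100, 200)], regions)
        assert hit.region.region_id == "a" and hit.dosage == "gain"
        [hit2] = genes_wholly_within([gene("g", 100, 200)], regions[::-1])
        assert hit2 == hit

    def test_chromosomes_do_not_mix(self):
        region = CnvRegion("chr2", 0, 1000)
        assert genes_wholly_within([gene("g", 100, 200, chrom="chr1")], [region]) == []

    def test_splitting_a_region_never_adds_containment(self):
        rng = np.random.default_rng(2)
        genes = [gene(f"g{i}", int(s), int(s) + 50) for i, s in enumerate(rng.integers(0, 950, 30))]
        whole = CnvRegion("chr1", 200, 800)
        split = [CnvRegion("chr1", 200, 500), CnvRegion("chr1", 500, 800)]
        in_whole = {c.gene_id for c in genes_wholly_within(genes, [whole])}
        in_split = {c.gene_id for c in genes_wholly_within(genes, split)}
        assert in_split <= in_whole


class TestEaseScore:
    @pytest.mark.parametrize("k", [0, 1])
    def test_zero_or_single_hit_cannot_score(self, k):
        assert ease_score(k, 50, 30, 500) == 1.0

    def test_matches_exact_hypergeometric_tail(self):
        # jackknife removes one hit before the upper tail
        assert ease_score(10, 100, 50, 1000) == pytest.approx(
            hypergeom_upper_tail(9, 100, 50, 1000), rel=1e-12
        )

    def test_jackknife_conservative_vs_plain_fisher(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            N = int(rng.integers(20, 300))
            n = int(rng.integers(2, N))
            K = int(rng.integers(1, N))
            k = int(rng.integers(1, min(n, K) + 1))
            assert ease_score(k, n, K, N) >= ease_score(k, n, K, N, jackknife=False)

    def test_plain_fisher_agrees_with_scipy(self):
        k, n, K, N = 8, 40, 60, 400
        table = [[k, n - k], [K - k, N - n - K + k]]
        _, p = fisher_exact(table, alternative="greater")
        assert ease_score(k, n, K, N, jackknife=False) == pytest.approx(p, rel=1e-9)

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            ease_score(10, 5, 50, 100)


class TestEnrichCategories:
    annotation = {
        "concentrated": ["a", "b", "c", "d"],
        "diluted": ["a", "x1", "x2", "x3", "x4", "x5", "x6", "x7"],
        "twin_b": ["b", "c", "x1", "x2"],
        "twin_a": ["b", "c", "x1", "x2"],
        "unrelated": ["y1", "y2"],
    }
    background = ["a", "b", "c", "d"] + [f"x{i}" for i in range(1, 8)] + ["y1", "y2", "z1", "z2"]

    def test_concentrated_category_ranks_first(self):
        results = enrich_categories(["a", "b", "c", "d"], self.annotation, self.background)
        assert results[0].category == "concentrated"
        assert results[0].rank == 1
        # zero-hit category is not tested
        assert "unrelated" not in {r.category for r in results}

    def test_single_hit_category_ranks_last_with_p_one(self):
        results = enrich_categories(["a"], self.annotation, self.background)
        assert all(r.ease_p == 1.0 for r in results)  # every category has k <= 1 here

    def test_bonferroni_over_tested_categories_only(self):
        results = enrich_categories(["a", "b", "c", "d"], self.annotation, self.background)
        n_tests = len(results)
        for r in results:
            assert r.bonferroni_p == pytest.approx(min(1.0, r.ease_p * n_tests))

    def test_identical_tables_tie_by_name(self):
        results = enrich_categories(["b", "c"], self.annotation, self.background)
        twins = [r for r in results if r.category.startswith("twin")]
        assert [t.category for t in twins] == ["twin_a", "twin_b"]
        assert twins[0].ease_p == twins[1].ease_p

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enrich_categories([], self.annotation, self.background)

    def test_list_outside_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            enrich_categories(["nope"], self.annotation, self.background)


class TestExportAndDosage:
    def test_export_selected_ranks_and_roundtrip_p(self):
        ann = TestEnrichCategories.annotation
        bg = TestEnrichCategories.background
        gene_list = ["a", "b", "c", "d"]
        results = enrich_categories(gene_list, ann, bg)
        exported = export_icnv_sets(results, [1, 2], ann, background=bg)
        assert [s.name for s in exported] == [results[0].category, results[1].category]
        # rescoring the exported set against the same list reproduces its ease_p
        re = enrich_categories(gene_list, {s.name: sorted(s.members) for s in exported}, bg)
        by_cat = {r.category: r.ease_p for r in re}
        original = {r.category: r.ease_p for r in results}
        for s in exported:
            assert by_cat[s.name] == pytest.approx(original[s.name], rel=1e-12)

    def test_export_none_is_empty(self):
        ann = TestEnrichCategories.annotation
        results = enrich_categories(["a", "b"], ann, TestEnrichCategories.background)
        assert export_icnv_sets(results, [], ann) == []

    def test_export_missing_rank_rejected(self):
        ann = TestEnrichCategories.annotation
        results = enrich_categories(["a", "b"], ann, TestEnrichCategories.background)
        with pytest.raises(ValueError, match="ranks"):
            export_icnv_sets(results, [99], ann)

    def test_export_then_filter_loses_no_shared_gene(self):
        ann = TestEnrichCategories.annotation
        bg = TestEnrichCategories.background
        results = enrich_categories(["a", "b", "c", "d"], ann, bg)
        exported = export_icnv_sets(results, [1], ann, background=bg)
        ranked = ranked_from_ids(["c", "a", "q1", "q2", "b"])
        fs = filter_set(exported[0], ranked)
        expected = set(ann[exported[0].name]) & {"c", "a", "q1", "q2", "b"}
        assert fs.members == expected

    def test_dosage_labels(self):
        genes = [gene("g_gain", 100, 200), gene("g_conflict", 300, 400), gene("g_unk", 500, 600)]
        regions = [
            CnvRegion("chr1", 50, 250, dosage="gain"),
            CnvRegion("chr1", 250, 450, dosage="gain"),
            CnvRegion("chr1", 280, 420, dosage="loss"),
            CnvRegion("chr1", 450, 650, dosage=None),
        ]
        containment = genes_wholly_within(genes, regions, all_witnesses=True)
        labels = annotate_dosage(["g_gain", "g_conflict", "g_unk", "g_missing"], containment)
        assert labels == {
            "g_gain": "gain",
            "g_conflict": "ambiguous",
            "g_unk": "unknown",
            "g_missing": "absent",
        }
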