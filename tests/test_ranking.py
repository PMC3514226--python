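"""Gene scoring and ranking against linkage markers."""

from __future__ import annotations

import numpy as np
import pytest

from pylogs.genome import GeneRecord, MarkerLocus
from pylogs.ranking import RankedGene, RankingConfig, gene_scores, rank_candidate_genes, rank_genes


def marker(cm: float, lod: float, chrom: str = "chr1", label: str = "m") -> MarkerLocus:
    return MarkerLocus(label, chrom, 0, 10, lod=lod, cm=cm)


def gene(gene_id: str, cm: float, chrom: str = "chr1") -> GeneRecord:
    return GeneRecord(gene_id, chrom, 0, 10, cm=cm)


class TestGeneScores:
    def test_lod_divides_raw_distance(self):
        [s] = gene_scores([gene("g", 30.0)], [marker(20.0, 2.0)])
        assert s.score == 5.0 and s.raw_cm == 10.0

    def test_gene_on_the_peak_scores_zero(self):
        [s] = gene_scores([gene("g", 20.0)], [marker(20.0, 4.0)])
        assert s.score == 0.0

    def test_minimum_over_lod_adjusted_distances(self):
        # distances 9 (LOD 3) and 16 (LOD 4) give adjusted {3.0, 4.0}
        [s] = gene_scores(
            [gene("g", 30.0)],
            [marker(21.0, 3.0, label="m1"), marker(46.0, 4.0, label="m2")],
        )
        assert s.score == 3.0 and s.raw_cm == 9.0

    def test_window_boundary_is_inclusive(self):
        cfg = RankingConfig(window_cm=50.0)
        [kept] = gene_scores([gene("g", 50.0)], [marker(0.0, 1.0)], cfg)
        assert kept.raw_cm == 50.0
        with pytest.raises(ValueError, match="larger window"):
            gene_scores([gene("g", 50.0001)], [marker(0.0, 1.0)], cfg)

    def test_window_applies_to_raw_not_adjusted_distance(self):
        # raw 60 > window even though 60 / LOD 6 = 10 is small
        with pytest.raises(ValueError, match="larger window"):
            gene_scores([gene("g", 60.0)], [marker(0.0, 6.0)], RankingConfig(window_cm=50.0))

    def test_markers_on_other_chromosomes_ignored(self, caplog):
        [s] = gene_scores(
            [gene("g", 10.0)],
            [marker(10.0, 3.0), marker(10.0, 100.0, chrom="chr9", label="far")],
        )
        assert s.score == 0.0

    def test_undefined_cm_rejected(self):
        with pytest.raises(ValueError, match="genetic position"):
            gene_scores([GeneRecord("g", "chr1", 0, 10)], [marker(1.0, 3.0)])


class TestRankGenes:
    def test_ascending_by_score(self):
        scores = [
            RankedGene("g1", 2.0, 2.0),
            RankedGene("g2", 1.0, 1.0),
            RankedGene("g3", 3.0, 3.0),
        ]
        ranked = rank_genes(scores)
        assert ranked.gene_ids == ["g2", "g1", "g3"]
        assert [g.rank for g in ranked] == [1, 2, 3]

    def test_ties_break_by_raw_cm_then_id(self):
        scores = [
            RankedGene("g_b", 4.0, 1.0),
            RankedGene("g_a", 4.0, 1.0),
            RankedGene("g_c", 3.0, 1.0),
        ]
        assert rank_genes(scores).gene_ids == ["g_c", "g_a", "g_b"]

    def test_single_gene_gets_rank_one(self):
        ranked = rank_genes([RankedGene("only", 0.5, 0.1)])
        assert len(ranked) == 1 and ranked[0].rank == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_genes([])


class TestProperties:
    @staticmethod
    def random_instance(rng, n_genes=None, n_markers=None):
        n_genes = n_genes or int(rng.integers(5, 101))
        n_markers = n_markers or int(rng.integers(1, 11))
        genes = [gene(f"g{i}", float(rng.uniform(0, 120))) for i in range(n_genes)]
        markers = [
            marker(float(rng.uniform(0, 120)), float(rng.uniform(3, 6)), label=f"m{j}")
            for j in range(n_markers)
        ]
        return genes, markers

    def test_matches_bruteforce_pair_enumeration(self):
        """Vectorized scoring equals a direct loop over all (gene, marker) pairs."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            genes, markers = self.random_instance(rng)
            cfg = RankingConfig(window_cm=50.0)
            got = {s.gene_id: (s.score, s.raw_cm) for s in gene_scores(genes, markers, cfg)}
            expected = {}
            for g in genes:
                best = None
                for m in markers:
                    raw = abs(g.cm - m.cm)
                    if raw > cfg.window_cm:
                        continue
                    adj = raw / m.lod
                    if best is None or adj < best[0]:
                        best = (adj, raw)
                if best is not None:
                    expected[g.gene_id] = best
            assert got.keys() == expected.keys()
            for gid in got:
                assert got[gid] == pytest.approx(expected[gid], rel=1e-12)

    def test_shrinking_window_monotone_and_order_preserving(self):
        rng = np.random.default_rng(8)
        genes, markers = self.random_instance(rng, n_genes=80, n_markers=5)
        previous = None
        for w in (50.0, 30.0, 10.0, 5.0):
            ranked = rank_candidate_genes(genes, markers, RankingConfig(window_cm=w))
            if previous is not None:
                assert set(ranked.gene_ids) <= set(previous.gene_ids)
                kept = [g for g in previous.gene_ids if g in ranked]
                assert kept == ranked.gene_ids
            previous = ranked

    def test_uniform_lod_matches_unnormalized_ranking(self):
        rng = np.random.default_rng(9)
        genes, _ = self.random_instance(rng, n_genes=60, n_markers=1)
        markers = [marker(float(rng.uniform(0, 120)), 4.0, label=f"m{j}") for j in range(6)]
        with_lod = rank_candidate_genes(genes, markers, RankingConfig(use_lod=True))
        without = rank_candidate_genes(genes, markers, RankingConfig(use_lod=False))
        assert with_lod.gene_ids == without.gene_ids

    def test_doubling_lod_halves_scores_keeps_ranks(self):
        rng = np.random.default_rng(10)
        genes, markers = self.random_instance(rng, n_genes=60, n_markers=4)
        base = rank_candidate_genes(genes, markers)
        doubled_markers = [
            MarkerLocus(m.label, m.chrom, m.start_bp, m.end_bp, m.lod * 2, m.cm) for m in markers
        ]
        doubled = rank_candidate_genes(genes, doubled_markers)
        assert base.gene_ids == doubled.gene_ids
        for a, b in zip(base, doubled):
            assert b.score == pytest.approx(a.score / 2, rel=1e-12)

    def test_gene_subset_yields_contiguous_ranks(self):
        rng = np.random.default_rng(11)
        genes, markers = self.random_instance(rng, n_genes=50, n_markers=3)
        full = rank_candidate_genes(genes, markers)
        subset = full.gene_ids[::3]
        restricted = rank_candidate_genes(genes, markers, RankingConfig(gene_subset=subset))
        assert sorted(restricted.gene_ids) == sorted(subset)
        assert [g.rank for g in restricted] == list(range(1, len(subset) + 1))
        # relative order matches the full ranking
        assert [g for g in full.gene_ids if g in set(subset)] == restricted.gene_ids
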