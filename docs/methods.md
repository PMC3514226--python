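# Methods

## Model and procedure

The package operationalizes a simple premise: if a pathway is involved
in a disease mapped by pedigree linkage, its member genes should
concentrate near the linkage peaks once distance is measured on the
genetic (centimorgan) scale and weighted by the strength of each peak.

**Coordinate assignment.** Genetic positions come from SNP landmarks
only; there is no interpolation between map SNPs. A gene's cM position
is the mean of the cM of the minimum-bp and maximum-bp SNPs strictly
inside the gene body (`[start, end)`, BED convention); a single inside
SNP stands alone; genes without inside SNPs carry no genetic position
and are excluded. This SNP-lookup rule trades smoothness for
faithfulness to how dense HapMap-style maps are actually used: with one
landmark every few kb, interpolation would change positions by far less
than the distances the method compares. A marker's cM is that of the
SNP nearest (in bp) to the floor-division midpoint of its reported
range; a distance tie resolves to the lower-bp SNP for determinism.
Marker ranges printed in literature tables are read as 1-based
inclusive and converted to the internal 0-based half-open convention.

**Scoring and ranking.** For each gene, candidate markers are the
same-chromosome markers whose *raw* genetic distance is within the
linkage window (inclusive); the gene's score is the minimum over
candidates of the LOD-adjusted distance. Two readings of the procedure
are possible — windowing before or after LOD adjustment — and the
package windows on the raw distance: the window is stated in
recombination units (50 cM ≈ the practical limit of detectable
linkage), so it is a property of the genetic distance itself, while the
minimum across peaks is taken over adjusted distances so a strong peak
can claim a gene from a nearer weak one. Ranking is ascending by score
with deterministic tie-breaking (raw distance, then gene id).

**Enrichment score.** The running-sum statistic is the unweighted
Kolmogorov–Smirnov form (+1/N_h at members, −1/(N−N_h) at
non-members, V = maximum positive deviation). Only positive deviations
count: the method asks whether a set concentrates *near the peaks*
(top of the list); bottom-of-list concentration has no meaning here.
An integer-sum variant (+(N−N_h)/−N_h, max positive sum) is exposed;
on equal-size sets it is the KS form scaled by N_h (N − N_h), so the
two order such sets identically.

**Permutation test.** Gene-to-rank assignments are shuffled with a
seeded generator; memberships and list length are preserved, and sets
are filtered to the universe before permuting so N_h is constant. Two
p-value modes: `top_rank` (fraction of permutations in which the set
attains the best V among all tested sets; ties for top each receive
credit, biasing p upward, i.e. conservatively) and `score_exceedance`
(per-set fraction of permutations with permuted V ≥ observed). Note
that under `top_rank` an exchangeable null set has p ≈ 1/K for K
tested sets — the mode measures "which set wins", not per-set surprise
— which is why the conventional exceedance mode is offered alongside.
p = 0 is stored as 0.0 and displayed as `< 1/n_perm`.

**CNV arm.** A gene qualifies for the CNV gene list only if some region
wholly contains it (half-open on both operands; equal boundaries count
as contained). Categories are scored with the EASE statistic: the
one-tailed Fisher exact (hypergeometric upper tail) after removing one
gene from the overlap, so single-gene overlaps can never score
(p = 1) and every p dominates the plain Fisher p. Bonferroni
correction multiplies by the number of categories with ≥ 1 hit —
zero-hit categories are not tests. The background universe defaults to
all genes in the annotation and is configurable, since EASE-style
analyses are sensitive to this choice. A gene contained in regions of
opposite dosage is labeled `ambiguous`; contained only in unlabeled
regions, `unknown`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `window_cm` | 50 cM | linkage window (inclusive); 50 cM ≈ 50% recombination, the practical limit of linkage detection |
| `use_lod` | true | divide distance by the marker's LOD score, letting stronger peaks claim more distant genes |
| `statistic` | `ks` | running-sum form; `integer` selectable |
| `mode` | `top_rank` | permutation p-value definition (see above) |
| `n_perm` | 1000 | permutations; p resolves to multiples of 1/n_perm |
| EASE `jackknife` | true | subtract one hit before the tail probability |

## The synthetic benchmark

The generator's defaults define the study conditions: five chromosomes
of 150 Mb spanning ~100 cM each (cM increments are exponential — the
map only needs monotonicity, which holds by construction), 1381
non-overlapping genes per chromosome (6905 total, every gene guaranteed
a map SNP at the default `gene_snp_fraction` of 1), 15 000 SNPs per
chromosome, 29 linkage loci (round-robin across chromosomes, centered
in the middle 40% of each, LOD uniform in (3, 6]), and 191 gene sets of
50–150 members. One *planted* set draws 90% of its members from genes
within 2 cM of a marker, cycling across markers so the signal spreads
over different peaks; the rest of the collection is exchangeable null.
The CNV generator designates 300 genes and builds one region per gene,
extending into the flanking intergenic gaps for the contained fraction
(so containment recovers the designated subset exactly at fraction 1.0)
and starting strictly inside the gene for the remainder (overlap
without containment). Set sizes were fixed at 50–150 so that even a
5 cM window leaves null sets with enough surviving members for their
V null distribution to stay well below the planted set's.

What the generator does **not** emulate: linkage disequilibrium and
realistic SNP spacing, overlapping genes, sex-specific or fine-scale
recombination variation, correlated gene-set collections (real pathway
databases share many genes between sets), and case/control CNV
frequencies. Passing the benchmark therefore shows the machinery is
correct and the method recovers a strong planted signal under clean
conditions; it does not certify power or error control on real genomes.

## Numerical choices

* The running sum can only attain a new positive maximum immediately
  after a member, so V is evaluated at member positions only
  (O(N_h log N_h) per set after sorting) — exact, not an approximation.
* The integer-sum variant is computed in integer arithmetic; the KS
  variant in double precision (agreement with the walk oracle to
  1e-12).
* EASE uses `scipy.stats.hypergeom.sf`; tests cross-check against an
  exact integer-arithmetic tail sum.
* Ties: gene ranking by (score, raw distance, id); set tables by
  (V descending, name) and (p ascending, name); marker SNP ties to the
  lower bp. All outputs are deterministic given the seed.
* Degenerate inputs: sets empty after filtering or covering the whole
  universe are skipped with a notice; a window retaining no gene is an
  error suggesting a larger window; a map chromosome with no SNPs
  leaves its genes without positions, which surfaces downstream as an
  empty-universe error.

## Design choices where the design was open

* The window boundary is inclusive (a gene at exactly 50 cM is kept)
  and configurable; the exact boundary affects only genes precisely on
  it.
* `top_rank` tie credit goes to every tied set (conservative).
* The pipeline prefixes exported CNV-derived set names with `iCNV:` to
  avoid collisions when the annotation and the a priori collection are
  the same file.
* `genes_wholly_within` reports the first witness region by coordinate;
  dosage annotation can request all witnesses to detect conflicts.
* The benchmark plants a single signal set; the aggregation of several
  CNV-derived categories is exercised by the export/merge round-trip
  instead.

## Known limitations

* LOD scores are inputs; the package does not recompute linkage.
* The enrichment score's absolute scale depends on the chosen variant;
  compare V values only within one statistic and one universe.
* `top_rank` p-values are comparable only within one collection (they
  depend on K).
* Flat annotation only: no ontology-graph propagation for categories.
* No genome-build liftover; all inputs must share one build and one
  chromosome naming scheme.
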