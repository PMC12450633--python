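# Methods

## Problem setting

Chronic disease can remodel the liver's cellular microenvironment. Given
single-cell RNA clusters annotated as hepatocytes, accessible-chromatin
peaks with positional categories, and bulk histone ChIP-seq peak sets, the
package (i) consolidates clusters into disease- and normal-skewed
hepatocyte subtypes, (ii) extracts condition marker genes, (iii) promotes
accessible peaks to promoter/enhancer status from histone evidence, and
(iv) assembles TF–CRE–gene regulatory networks filtered by independent
evidence layers. All stages operate on post-upstream tables: clustering,
differential expression, peak calling and positional annotation are inputs,
not steps.

## Coordinates and overlap

All intervals are 0-based half-open (BED convention); abutting intervals do
not overlap. Overlap requires `min(end_a, end_b) − max(start_a, start_b) ≥
min_bp` on the same chromosome, with `min_bp = 1` by default (the bedtools
`intersect` default; no overlap fraction is imposed). Strand never enters
overlap arithmetic — ATAC and histone peaks are unstranded — and matters
only for the sign of TSS-relative distances. Chromosome names are compared
as exact strings; `normalize_chrom_names` handles mixed "chr1"/"1" inputs.
Histone tracks are used as read, without pre-merging overlapping intervals.
Repeated queries go through a per-chromosome interval tree; correctness is
checked in the tests against an exhaustive all-pairs oracle.

## Subtype consolidation

Each hepatocyte cluster `i` is summarised by its top-k upregulated gene set
`c_i` (default k = 20): genes with `avg_log2FC > 0` and `p_val < 0.05`,
sorted by `avg_log2FC` descending, ties broken by gene symbol so the result
is deterministic. Filtering precedes sorting; the unadjusted `p_val` column
is used. Similarity is the Jaccard index `J = |c_i ∩ c_j| / |c_i ∪ c_j|`
(defined as 0, with a warning, when both sets are empty — a case real data
never produces). Clusters whose off-diagonal similarity row is identically
zero are excluded before clustering: a cluster sharing no top genes with
any other is not the same cell type. The remainder are clustered
agglomeratively on distance `1 − J` with **complete linkage** (the default
of the pheatmap-style tools this mirrors) and the tree is cut at exactly
`n_subtypes = 2` groups rather than at a height threshold, because the
analysis targets a two-subtype split. Labels are assigned by descending
group size (smallest member id breaks ties), so `Subtype_1` is always the
larger, disease-skewed group. The assignment is invariant to input cluster
order up to this labelling rule.

## Condition markers

`upregulated_in_condition` applies the same (fc, p) filters to a named
disease-vs-normal contrast. Markers are the intersection of that set with
the **union** of the supplied pathway gene sets (the union reading of the
pairwise pathway Venn; the alternative intersection reading would only
shrink the marker set and is not used). Gene matching is case-sensitive
exact match with an optional uppercase-normalisation flag. Pathway
membership arrives as GMT input; enrichment p-values are out of scope.

## CRE annotation

- promoter := peak category `Promoter` AND ≥ 1 bp overlap with H3K4me3;
- enhancer := peak category ∈ {Distal, Exonic, Intronic} AND overlap with
  H3K4me1 AND overlap with H3K27ac.

Any-part overlap is used (the summit is not required to be covered). The
category requirement makes the classes disjoint. Gene assignment is a
positional fallback: a promoter is assigned to the nearest TSS lying inside
the peak or within 2,000 bp of its boundaries (the canonical promoter
window upstream of the TSS); an enhancer to the nearest TSS within
100,000 bp of the peak midpoint, else left unassigned. Distances are
measured TSS → peak midpoint, signed negative when the peak is upstream on
the gene's strand; equidistant TSSs resolve to the lexicographically
smaller symbol. Authoritative enhancer→gene links come from the evidence
tables in the network stage, not from distance.

## Peak statistics

Category composition per condition is tested with the Pearson chi-squared
statistic `Σ (obs − exp)² / exp` on the condition × category table, no
continuity correction, `df = (r−1)(c−1)` (3 for two conditions × four
categories — counts at this scale are large, so Yates' correction would
only bias the statistic downward). Peaks with category `NA` are tallied
separately and excluded from the test; a zero margin is an error naming the
degenerate row/column. Histone match fractions report the share of peaks
overlapped by ≥ 1 track interval; matched + unmatched = 1 for non-empty
peak sets. Gene coverage assigns peaks to TSS ± 50 kb windows — the
gene-region extent behind such coverage summaries is rarely stated by
upstream tools, so it is an explicit, configurable parameter rather than a
guess — with peaks spanning two windows counting for both genes, and
reports per-category gene sets, their 15-region Venn by
inclusion–exclusion, per-category maxima of peaks per gene, and genes
covered by all four categories.

## Networks

**Motif enrichment.** For a motif present in `K` of `N` background peaks
and `k` of `n` target peaks, `p = P(X ≥ k)` under the hypergeometric
distribution, computed by `scipy.stats.hypergeom.sf(k−1, N, K, n)`;
fold = `(k/n)/(K/N)`. Benjamini–Hochberg correction is applied across
motifs within each CRE set independently (promoters and enhancers are
reported side by side, not pooled); the BH step-up is implemented directly
and cross-checked against statsmodels in the tests. Targets must be a
subset of the background.

**Promoter network.** Edge (tf → promoter-peak → gene) iff the gene is
condition-upregulated, owns a histone-supported promoter call, the TF motif
occurs in that peak, and the TF is in the configured TF universe (default:
all motifs in the occurrence table, standing in for the variable-gene
list). Self-loops (tf = gene) are kept but flagged. Multiple promoters per
gene yield one edge per (tf, peak, gene) triple.

**Enhancer network.** An inferred link survives iff some curated link
overlaps its enhancer by ≥ `min_bp` **and** targets the same gene
(`require_gene_match=False` relaxes to coordinate overlap alone — the
stricter both-conditions reading is the default), and the enhancer overlaps
a histone-supported enhancer call. Venn counts over
{inferred, curated-supported, histone-supported} are reported both per
enhancer–gene link and per unique enhancer region, since the two countings
differ whenever one region carries several links.

## Synthetic data: what it emulates and what it does not

The generator plants every downstream answer at roughly 1/10 of the
source-study scale (defaults: 12 hepatocyte clusters, 2,000 annotated
genes, 2,000 peaks per condition on a 2 × 5 Mb genome) so the full pipeline
runs in seconds:

- **DEG blocks.** Two cluster blocks (7 + 4 clusters, echoing the reported
  subtype memberships) share exactly 10 of their top-20 genes within a
  block and none across blocks, forcing within-block `J = 10/30 = 1/3`; an
  outlier cluster shares nothing (J = 0) and must be excluded. Filler genes
  fail exactly one of the two upregulation filters, so the top-k sets are
  forced by construction. `p_val` is generated, not computed from counts:
  the generator emulates post-DE tables, and DE testing is out of scope.
- **Cells.** Per-cluster disease fractions default to 0.853 for the
  disease-skewed block and 0.12 for the normal-skewed block — the reported
  condition skews of the two subtypes (85.3% disease; 88% normal).
- **Peaks and histone.** The genome is tiled into 2 kb slots; each peak
  occupies the first half of its own slot and its histone evidence never
  leaves the slot, so planted truth is exact. Planted promoter/enhancer
  rates are 15% / 12.5% in the disease state (30 and 25 at the 200-peak
  test scale) and lower in the normal state, echoing the reported asymmetry
  of calls between states. Decoys carry a single enhancer mark, enhancer
  marks on a Promoter-category peak, or H3K4me3 on a non-Promoter peak.
  Background category frequencies default to the reported Promoter-share
  contrast (16.8% disease vs 8.3% normal); note the planted CREs shift the
  realised composition above these background rates.
- **Genes and motifs.** Every disease planted-promoter peak hosts a gene
  TSS at its midpoint; the first six are the named network genes (the five
  canonical markers plus one more upregulated gene). The CYP3A4 promoter
  carries exactly five planted TF motifs; other network promoters 1–3.
  Random motif scatter (density 0.05 per TF across 16 liver-relevant TFs)
  avoids the network-gene peaks, and upregulated filler genes exist only in
  expression space, so the planted promoter edges are provably the complete
  rule-satisfying set.
- **Links.** Of 100 inferred links, 60 get a curated partner (same gene,
  jittered overlapping coordinates) and 40 of those sit on planted-enhancer
  coordinates; 20 curated-only decoys are added. Non-histone link
  coordinates live in dedicated peak-free slots, so the triple intersection
  is exactly the 40 planted edges. Link targets are drawn without
  replacement, keeping edges distinct.

What the generator does **not** emulate: count-level noise, doublets,
batch effects, fragment-size structure, correlated motif co-occurrence,
overlapping peaks, or peaks/genes sharing loci across conditions in any
biologically meaningful way. Passing recovery tests therefore demonstrates
the correctness of the rules and plumbing under clean planted conditions,
not robustness to upstream noise — the published headline counts
(e.g. 163,166 peaks, 983/1,642 promoter/enhancer calls) depend on the
original accessions and upstream tools and are deliberately not targets.

Determinism: one integer seed feeds `numpy.random.SeedSequence(seed,
spawn_key=(stage,))` with a fixed stage enumeration (DEGs = 0, cells = 1,
disease peaks = 2, normal peaks = 3, genes = 4, motifs = 5, links = 6,
condition DEGs = 7), so bundles are byte-identical across runs and adding a
stage never perturbs earlier ones.

## Pipeline and numerical choices

Stages run in dependency order; each writes TSV/JSON artifacts plus a
`manifest.json` with a config hash (output location excluded from the hash,
since where files land must not change what they contain), the seed, and
sha256 checksums of all inputs and outputs. No stage is stochastic, and all
outputs are written in sorted, fixed-format order (`%.6g` floats,
`sort_keys` JSON), so reruns are byte-identical — verified by checksum in
the tests. Degenerate inputs are handled explicitly: empty peak sets flag
undefined fractions, empty-vs-empty Jaccard warns and returns 0, zero
chi-squared margins and missing stage inputs raise errors naming the
offender.

## Known limitations

- Gene assignment ignores transcript structure; a TSS-anchored window is a
  simplification of real promoter architecture.
- The chi-squared test treats peaks as independent observations, as the
  descriptive comparison it mirrors does.
- The enhancer filter takes the inferred links' TF attribution at face
  value; no motif check is re-applied to enhancer edges.
- The 50 kb gene-coverage window and 100 kb enhancer assignment cutoff are
  conventional defaults, not fitted values; both are parameters.
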