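# Methods

## The screen

`clusterscout` formalizes a two-stage screen for candidate specialized-
metabolism loci in plant genomes.

**Stage 1 — neighborhood detection.** The unit of analysis is a gene (GFF3
feature of type `gene`; transcript features are ignored). Genes carrying one
of the five signature enzyme-family labels — cytochrome P450 (P450),
2-oxoglutarate-dependent dioxygenase (2ODD), terpene synthase (TPS),
polyketide synthase (PKS) and UDP-sugar dependent glycosyltransferase
family 1 (UGT) — are chained left-to-right per chromosome. Two consecutive
family genes join one chain iff

* the number of (necessarily unlabelled) genes between them in genomic order
  is ≤ `max_intervening`, and
* the distance from the end of the earlier gene to the start of the later
  one is ≤ `max_gap_bp` (overlapping or nested genes count as distance 0).

Maximal chains with ≥ `min_genes` members are emitted as regions. Because
the chain relation links only consecutive family genes, every family gene
belongs to at most one region, regions are maximal by construction, and
detection is equivalent to taking connected components of the
consecutive-pair constraint graph — the independent oracle used in the test
suite. Strand is parsed and carried but never used: characterized plant
clusters mix gene orientations.

**Classification.** A region with ≥ `min_distinct_families` (default 2)
distinct labels is a `multi_family_cluster`; otherwise it is a
`single_family_tandem` with its dominant family recorded. A separate
`strict_cluster` flag marks ≥ 3 distinct families — the classical
definition of a biosynthetic gene cluster. The default threshold is 2, not
3, because the five-family gene universe cannot see non-signature enzyme
classes (BAHD or SCPL acyltransferases, for example): the thalianol cluster
contains a TPS, three P450s and a BAHD acyltransferase, and would be missed
at ≥ 3 within this universe. Survey summaries count clusters and per-family
tandem arrays; cluster + Σ tandem = total holds by construction.

**Stage 2 — co-expression.** Raw non-negative expression values are
transformed to log2(x + pseudo_count); genes expressed in fewer than
`min_expressed_samples` (default 3) samples, and zero-variance genes, are
dropped. Pearson correlation is computed over the union of candidate-region
genes by default (a `restrict_to_regions` flag switches to genome-wide
mode). Each gene ranks its partners by descending correlation (fractional
ranks on ties — symmetric and deterministic) and the mutual rank
MR(i,j) = √(rank_i(j)·rank_j(i)) scores each pair, following the ATTED-II
convention with its customary threshold MR ≤ 30. An optional conjunctive
correlation floor `pcc_min` is available, and matters in region-restricted
mode: with only ~20 candidate genes every MR is ≤ n−1 < 30, so MR alone
saturates to a complete graph, and the floor carries the screen (the demo
uses `pcc_min = 0.5`). Connected components of the thresholded network —
not any density-based clustering — define "co-expressed networks"; a region
qualifies when ≥ `min_coexpressed_members` (default 3) of its members lie in
one component. Region members missing from the expression matrix are
tolerated and counted as not-in-network.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `max_gap_bp` | 50 000 | bp | characterized plant clusters span tens of kb |
| `max_intervening` | 3 | genes | clusters tolerate a few interspersed non-enzyme genes |
| `min_genes` | 3 | genes | "at least three" members defines the smallest region of interest |
| `min_distinct_families` | 2 | families | see classification note above; strict ≥ 3 flag reported separately |
| `mr_max` | 30 | rank | customary mutual-rank cutoff for confident co-expression |
| `pcc_min` | off | r | conjunctive floor; needed when the network is restricted to a small candidate set |
| `min_coexpressed_members` | 3 | genes | smallest component worth calling a co-expressed cluster |
| `pseudo_count` | 1 | expression | log2(x+1) transform |

No published proximity constants exist for this survey, so `max_gap_bp` and
`max_intervening` are explicit, logged flags rather than buried constants.

## Synthetic data: what it emulates, and what it does not

`simulate_genome` plants multi-family clusters and single-family tandem
arrays (default: five regions — a thalianol-style TPS/P450/P450/UGT cluster
and a P450/2ODD/UGT cluster, both co-regulated; a PKS/P450/P450 cluster, a
UGT×4 array and a P450×3 array, not co-regulated) among 200 background genes
on three 1.2-Mb chromosomes. Placement honours a noise-free contract: every
planted region sits inside an exclusion buffer 60 kb wide on each side
(wider than the 50-kb chaining gap), and background family labels are
thinned so that no two labelled background genes are within chaining
distance of each other either. Under this contract the default detector
provably recovers exactly the planted truth — which is what the recovery
tests assert. Background gene positions are uniform within the free
intervals with a minimum intergenic spacing (sorted-uniform-offset
placement, exact); products are generated to match the default keyword
rules, so the keyword assigner reproduces the ground-truth catalog.

`simulate_expression` uses a one-factor linear latent model per co-regulated
region: on the log2 scale, member value = baseline_g + b·f_s + ε with
f_s ~ N(0,1) per sample and ε ~ N(0,σ²), giving expected within-region
correlation b²/(b²+σ²) and expected between-region correlation 0. The
matrix is exported on the raw scale as 2^value − pseudo_count clipped at 0,
so preprocessing recovers the latent values exactly wherever no clipping
occurred. Defaults — 50 samples, b = 2, σ = 1 (expected r = 0.8), baseline
mean 6 and sd 1.5 log2 units — emulate the strong co-regulation of
characterized biosynthetic clusters over a compendium-scale profile.

What passing these tests does **not** show about real data: real genomes
have no isolation buffers (nearby background family genes merge or extend
regions, so precision < 1 is expected), family assignment from annotation
text is noisy, expression compendia have batch structure, dropouts and
non-Gaussian noise, and co-regulation is condition-specific rather than a
single global factor. The generator validates the machinery, not the field
performance of the defaults.

## Numerical and design choices

* Coordinates are 1-based inclusive on every public type (the GFF3
  convention); interval arithmetic converts internally.
* Gene sorting ties break by (end, gene_id); chromosome names are opaque
  strings (no natural-sort assumptions). All randomness flows through
  `numpy.random.default_rng(seed)`; identical inputs give byte-identical
  exports.
* Correlations are symmetrized ((C + Cᵀ)/2) and clipped to [−1, 1] to absorb
  floating-point asymmetry before ranking.
* Monotonicity: loosening `max_gap_bp` or `max_intervening` can only merge
  maximal chains, so the *chain* count (singleton family genes included) is
  non-increasing and the member coverage of emitted regions is
  non-decreasing. The emitted-*region* count itself is not monotone — a
  looser gap can promote two sub-threshold singletons into a brand-new
  region — which is why the invariant tests count chains.
* Region/truth matching is greedy one-to-one on descending member-set
  Jaccard (threshold 0.5); empty-vs-empty scores 1.0 by convention.
* A curated family table always overrides keyword assignment. Keyword rules
  are first-match-wins, case-insensitive substring.

## Problem sizes

The test suite and acceptance script run the detector-oracle comparison on
30 random genomes of ≤ 200 genes, mutual-rank exactness up to 50 genes, the
correlation calibration at 200 samples, and the end-to-end demo (217 genes,
50 samples) across three seeds — desk-scale sizes chosen so the whole suite
completes in seconds while exercising every code path.

## Known limitations

* Family assignment is annotation-text- or table-based only; no
  protein-domain (HMM) scanning, and no sequence handling at all.
* "Same biosynthetic pathway" membership is not computable from an
  annotation; multi-family proximity is a proxy.
* No synteny or cross-species comparison; no GTF dialects; no querying of
  live co-expression services; no normalization beyond the log transform.
* Component-based network modules are the simplest faithful reading of
  small disconnected co-expression subnetworks; denser compendia may need
  community detection, which is out of scope.
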