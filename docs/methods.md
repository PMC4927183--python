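# Methods

This note documents the models, default parameters and numerical choices
behind `regencirc`, and what the synthetic-data generator does and does
not emulate.

## Study design assumptions

The package targets a three-species comparison with one *anchor* species
(zebrafish) sequenced in replicate (default 3 control + 3 regenerating
libraries) and two species (bichir, axolotl) with one library per
condition. All cross-species statements are made in the anchor species'
namespace: miRNAs are identified across species by exact mature-sequence
equality (the mature product is the conserved unit; near-identical
sequences are deliberately kept distinct because a single seed-region
change retargets a miRNA), and genes through a provided ortholog map, with
a reciprocal-best-hit helper for building one from similarity tables.
When several transcripts map to one anchor gene, the transcript with the
highest mean expression (log2 CPM) represents the gene.

## Small-RNA processing

Reads are processed in DNA space (U→T on input). Adapter clipping removes
the leftmost occurrence of the 3′ adapter — the full adapter anywhere in
the read, or a 3′-terminal adapter prefix of at least `min_overlap` bases
(default 5) — allowing `max_mismatch` mismatches (default 1). Reads
without any adapter occurrence are discarded: for inserts shorter than
the read length the adapter must be present, and keeping adapter-less
reads would bias the tag population toward long inserts. Quality trimming
truncates at the first base below Q20 (first-failure rule; simplest
defensible policy, threshold configurable). Surviving inserts are
collapsed into unique tags, keeping lengths 20–25 nt, the size range of
mature miRNA products.

## Tag annotation and isomiR classes

A tag is matched against each catalog entry by sliding it along the
mature sequence: terminal 5′ shifts up to ±2 nt, 3′ shifts up to ±3 nt,
and at most 2 substitutions within the overlap (tolerances follow common
isomiR conventions and are configurable; internal indels are treated as
no-hit, keeping the matcher exact and fast). The best hit minimizes
(substitutions, |5′ shift| + |3′ shift|) lexicographically; ties resolve
by catalog order, which is therefore part of the interface. Variant
classes: `canonical`, `5p_shift`, `3p_shift`, `internal_sub`, `seed_sub`
(any substitution at mature positions 2–8, 1-based), `multi`. Tags
missing the catalog are assigned `tRF`/`rRF` only on exact, full-length
substring identity to a tRNA/rRNA reference on the given strand —
a deliberately conservative rule for calling processed fragments.

Conserved tags are those present (count ≥ 1 by default) in *every* sample
of *every* species; the floor is configurable because "expressed" is a
judgment call at low depth.

## Differential expression

Counts are normalized to counts per million (plain CPM; no trimmed-mean
scaling factor is applied, though the interface leaves room for one).
Log fold changes use a pseudocount of 0.5 on the CPM scale to keep
unreplicated log ratios finite.

For the replicated design the test is a conditional negative-binomial
exact test: with common per-sample dispersion φ (variance μ + φμ²; φ = 0
is Poisson), the two group sums of library-size-equalized counts are NB
with means proportional to group size and dispersion φ/n. Conditioning on
the total T, the two-sided p-value sums the probabilities of all splits
at most as probable as the observed one, with the per-sample mean taken
as T/(n₁+n₂). At φ = 0 this reduces exactly to the two-sided binomial
test on the split. φ is estimated once per matrix as the median over
features of the method-of-moments quantity max(0, (s² − m̄)/m̄²) from
within-group variances — the smallest model that makes the exact test
well-defined; no tagwise or trended shrinkage is attempted. Significance
is FDR < 0.05 (Benjamini–Hochberg); raw p-values are also reported.
The discrete test with a plug-in dispersion is slightly anti-conservative
at the raw-p level for 3-vs-3 designs (~7% at nominal 5% in the bundled
null simulations) while the BH-flagged discovery rate stays far below
nominal; both are exercised in the test suite.

Unreplicated species get fold-change-only calls: up iff log2FC > +0.58,
down iff log2FC < −0.58, strictly. Two sharing rules exist for
cross-species concordance because single-replicate fold changes can be
trusted at different stringencies: `sign_only` (any agreeing sign) is the
default when a significant anchor species backs the call, `threshold`
(strict |log2FC| > 0.58 in both) when two unreplicated species are
compared directly. Features are assigned to the *largest* concordant
species subset (all-species, then anchor+other pairs, then anchor-only),
making the partitions disjoint and exhaustive over the anchor's
significant features.

## Target prediction

Canonical sites follow seed-match nomenclature on the given UTR strand
(3′-UTRs are single-stranded; no reverse-complement scanning): 6mer =
Watson–Crick match to miRNA positions 2–7, 7mer-m8 adds position 8,
7mer-A1 adds a target-side A opposite position 1, 8mer both. One locus
reports only its highest class. The nucleation-bulge (pivot) class
accepts exactly one unpaired target nucleotide between the target bases
pairing miRNA positions 5 and 6, detected by enumerating the four
single-base insertions into the 7mer-m8 match pattern. Coordinates are
0-based half-open on the UTR, 1-based on the miRNA.

Candidate sites are scored with a deterministic local anti-parallel
alignment (Gotoh affine gaps): match +5, G:T wobble +1, mismatch −3, gap
open −8, gap extend −2, substitution contributions doubled at positions
2–8; a perfect 22-nt duplex scores 145. The biological claims downstream
rest on site presence/absence, not on a particular score value, so the
scheme is intentionally simple and fully specified; `min_score` defaults
to 80 for genome-scale scans, while the synthetic pipeline (whose
background is seed-free by construction) runs at 0. Regulatory pairs are
kept only when miRNA and target change expression in opposite shared
directions.

## Networks and enrichment

The anchored subnetwork keeps interaction-table edges (scores taken
as-is, STRING-style 0–1000 assumed but not required) whose endpoints lie
in anchors ∪ candidates and that touch at least one anchor gene;
self-loops and duplicate unordered pairs are dropped, and anchor nodes
persist even when isolated. The top-scoring core retains edges *strictly*
above the nearest-rank (1 − f) quantile of the edge scores (rank
⌈(1−f)·n⌉ of the ascending order, default f = 0.02); ties at the
threshold are excluded, so an all-tied network keeps nothing. Regulatory
miRNA→gene edges are overlaid idempotently with the best duplex score;
node fold-change attributes use the anchor species' log2FC. Enrichment is
a one-sided hypergeometric upper tail per flat category (no ontology
propagation) with BH-FDR across categories.

## Synthetic-data generator

The generator reproduces the design features the pipeline must cope
with, with machine-readable ground truth:

* **catalogs** — shared miRNAs carry identical 22-nt mature sequences in
  all member species; all seeds differ pairwise in ≥ 3 of 7 positions so
  no simulated miRNA can masquerade as an isomiR of another (rejection
  sampled; an infeasible request fails explicitly). Default sharing
  structure: 108 triple-shared, 16 per pair, 16 unique per species,
  mirroring the catalog overlap of the three regeneration models.
* **counts** — NB(μ, μ + φμ²) with φ = 0.1 by default, per-feature
  baseline abundances lognormal(σ = 1.5), library size 10⁶ tags per
  sample (depth per library is a conventional choice, not study-derived).
  Planted features scale the regenerating-group mean by 2^±2 by default,
  concordantly across species. Library sizes attached to the simulated
  matrices are the *designed* depths: planted effects are absolute
  expression changes rather than compositional reallocation, so CPM fold
  changes estimate the planted factors directly. Real libraries only
  approximate this, and strongly unbalanced regulation would require a
  robust scaling normalization that plain CPM does not provide — a known
  limitation, not exercised by the generator.
* **reads** — every tag copy is emitted exactly (tag + adapter + random
  tail at uniform Q40), so collapsing recovers the planted counts;
  isomiR variants (uniform over 5′ shift, 3′ shift, substitution at a
  uniform position, so seed variants arise naturally) and tRNA/rRNA
  fragments are appended on top at configurable per-read rates. There is
  no sequencing-error or quality-profile model.
* **UTRs** — backgrounds are rejection-sampled against every simulated
  miRNA's 6mer core and all four bulge patterns, and planted site chunks
  carry guard flanks pinning their class, so the recorded sites are
  *exactly* what a correct scanner must report: site-recovery tests are
  exact, not probabilistic. A site request whose fixed match region
  accidentally contains another miRNA's core is dropped rather than
  planted ambiguously.
* **interactions, orthologs, categories** — undirected distinct scored
  pairs with a configurable anchor-touching fraction; a 1:1 ortholog map
  covering 95% of genes; flat categories with one deliberately enriched
  in planted-up genes.

One seed sequence drives everything; sub-generators derive child streams
deterministically, and all file outputs are byte-identical under a fixed
seed. What passing synthetic tests do *not* show: robustness to
sequencing error, adapter variants, compositional normalization bias,
many-to-many orthology, or ontology structure — none of which the
generator emulates.

## Problem sizes in the bundled runs

The demo pipeline runs 30 shared + 12 non-shared miRNAs, 120 genes,
2 × 10⁴ tags per library across 8 libraries, completing in well under a
minute. The parameter-recovery check uses the full stated conditions (200
shared miRNAs, 50 planted up at log2FC = 2, φ = 0.1, 10⁶ tags/sample) at
the count level; the null-calibration check runs 200 replicate null
simulations of 500 features at 3 vs 3. Brute-force cross-checks
(NB-split enumeration to totals of 200, site-scan enumeration on ≤ 30-nt
windows, order-statistics and hypergeometric-tail oracles) back every
core primitive in the test suite.

## Known limitations

* The exact test uses a single common dispersion; tagwise variation makes
  raw p-values optimistic for small replicate numbers (quantified above).
* tRF/rRF calling by exact substring match cannot detect fragments with
  sequencing errors or non-templated additions.
* Duplex scores are alignment heuristics, not free energies; no
  conservation or accessibility filtering is applied.
* The two sharing rules are both reasonable; results near the ±0.58
  boundary depend on which is chosen, and both are surfaced in the
  configuration rather than resolved.
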