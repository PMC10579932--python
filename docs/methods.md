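# Methods

## Coordinates, contexts and the weighted level

Per-cytosine call tables are 1-based (CGmap-style: chrom, pos, strand,
context, methylated reads, total reads); BED/bedGraph outputs and all
in-memory intervals are 0-based half-open. Context is defined on the
cytosine's own strand from the two bases 3' of it: CG if the next base is
G, else CHG if the base after that is G, else CHH; a needed base that is N
or beyond the contig end leaves the context undefined and the site is
excluded. Contexts in a call file are trusted on read but can be
re-derived from the genome and cross-checked.

All region-level statistics use the weighted methylation level
`Rm = Nm/(Nm+Nnm)` — pooled methylated over pooled total reads across the
covered sites of one context in the region. Pooling makes Rm exactly
additive over disjoint intervals (a property-tested invariant) and weights
deep sites more than shallow ones; a region with no covered site has an
*undefined* level (never coerced to 0). CG sites on opposite strands are
two distinct sites; complementary-pair pooling is not applied, because the
level is defined per reference cytosine.

A site counts as "methylated" for context-share summaries when it has ≥ 1
methylated read at coverage ≥ 4. This is a reporting convention, not a
statistical test; both thresholds are arguments.

## Gene features

Each transcript is decomposed into upstream 2 kb, first exon, first
intron, internal exons, internal introns, last exon and downstream 2 kb,
all in transcription orientation and clipped at contig bounds. A
single-exon gene contributes only a first exon (no last/internal
features), and a two-exon gene has no internal features, so the classes
stay disjoint. "Promoter" is defined as the upstream 2 kb of the TSS —
the length is a convention (configurable), chosen to coincide with the
upstream feature. Feature profiles pool counts over all intervals of a
label genome-wide after merging overlaps (weighted pooling, not a mean of
per-gene means). Time-course tracks are normalised per feature by the row
sum, so each row reads as the share of that feature's methylation at each
time point; an all-zero row is returned unchanged and flagged.

Chromosome-scale maps tile the genome in 10 kb windows and render the
weighted level on a 0–20 colour scale (level × 20); this is purely
presentational and both window and scale are arguments.

## DMR calling

Windows are non-overlapping 1 kb tiles by default (a sliding mode with
step = window/2 exists but is off: tiling keeps "neighbouring window"
unambiguous for merging). A window passes when

1. it holds ≥ 5 covered sites of the context in *each* group,
2. the fold change between weighted levels is ≥ 2,
3. the two-sided Fisher exact P on the pooled table
   [[Nm1, Nnm1], [Nm2, Nnm2]] is < 0.05, and
4. neither group is hypomethylated — read literally: both levels ≥ the
   floor (default 0.05). The laxer reading (at least one group above the
   floor) is available via `hypo_rule="either"`.

Fold changes use the floor as a pseudo-level lower bound, which prevents
division by zero without distorting ratios above the floor. The Fisher P
is the sum of hypergeometric probabilities of all same-margin tables whose
probability is ≤ the observed one within a relative tolerance of 1e-7 (the
tolerance absorbs floating-point ties); it is computed from the
log-hypergeometric PMF over the support and is checked in the tests
against exact enumeration for every table with total ≤ 40 and against an
independent library implementation.

Merging: two neighbouring passing regions — same chromosome, context and
direction of change, consecutive, gap ≤ 1000 bp (one window; configurable)
— are combined when the counts pooled over the whole span, recomputed from
the raw calls (the gap's sites included), still pass the fold, P and floor
criteria. Passes run strictly left-to-right and restart after every merge;
the loop terminates at a fixed point, so the final set is pairwise
non-mergeable and the operation is idempotent (both are asserted on random
scenarios). Direction is sign(Rm2 − Rm1); opposite-direction regions are
never merged. No multiple-testing correction is applied by default,
matching the raw-threshold design; BH adjustment is available.

A gene is a gene-body DMG when ≥ 1 DMR overlaps its TSS-to-end span by
≥ 1 bp, and a promoter DMG for the upstream 2 kb; one gene can be both,
and tallies count distinct genes per location.

## Enrichment

Term over-representation uses the upper hypergeometric tail
P(X ≥ k) with N the universe size, K the term's universe genes, n the DMG
set and k their overlap. The universe defaults to all genes appearing in
any mapping — the background set is a genuine modelling choice; passing an
explicit universe (e.g. all genes with covered cytosines) is supported,
and a DMG absent from the universe is an error rather than a silent drop.
Gene-body and promoter DMG sets are tested separately per comparison.

## Degree of difference

`score = log2(Rm1)/log2(Rm2)`, with any zero input replaced by 0.001
before the logs. The formula is a ratio of logs, *not* the log of a ratio;
it is implemented exactly as defined. When the denominator level is 1
(log2 = 0) the score is flagged infinite rather than raising, and
score(x, x) = 1 identically.

## 7-mer sequence preference

For every covered site, the 7-mer read on the site's own strand with the
cytosine at position 4 is looked up in the genome; sites whose flanks run
off the contig or contain N are excluded and tallied, so the reported site
counts plus exclusions exactly partition the covered-site set. Per 7-mer
the default statistic is the pooled weighted level; "methylation
percentage" could also mean the fraction of sites methylated, so that
variant is exposed as `statistic="site_fraction"`.

## BSP clone analysis

Clones are aligned globally to the reference amplicon (match +1, mismatch
−1, gap −2) with one asymmetry: clone T opposite reference C scores as a
match, because bisulfite converts unmethylated C to T. BSP amplicons are
short, so end-to-end alignment is appropriate. If direct-orientation
identity is below 0.5 the reverse complement is tried; clones below 0.8
bisulfite-aware identity are rejected with a reason. At each reference CpG
a clone C is methylated, T unmethylated, anything else missing; the
conversion rate is the fraction of non-CpG reference cytosines read as T,
and clones below 0.95 conversion fail QC (QC is on by default but
optional — some studies keep all clones). Only the top, primer-defined
strand is modelled. The simulator inverts the same chemistry (methylated
CpG Cs stay C; unmethylated and non-CpG Cs convert with the given rate),
and the caller provably inverts it: at conversion rate 1.0 the round trip
is lossless for any planted pattern, and at rate r < 1 the false-methylated
fraction at unmethylated CpGs converges to 1 − r (both property-tested).

## The synthetic methylome generator

The generator emulates a mosaic, CG-dominated invertebrate methylome. Its
defaults define the package's reference study:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 500 kb, GC 0.35 | desk-scale stand-in for a mollusc assembly |
| genes | 40 × 4 exons (300 bp exons, 500 bp introns) | placed on a jittered grid, never overlapping |
| CpG islands | 1 per promoter, 600 bp | CG-enriched sequence written 5' of the TSS |
| repeats | 10% of the genome, 2 kb units | annotation intervals in intergenic space |
| groups | control + one post-graft group | states shared, reads drawn per group |
| coverage | Poisson, mean 30× | exercises the site-count filters genuinely |
| planted DMRs | 20 × 1 kb, CG, 0.3 vs 0.7 | window-grid aligned, ≥ 2 kb apart |

Site methylation is bimodal, as in real methylomes: a site is methylated
with a probability set by its context × feature class (CG: 0.70 in gene
bodies and repeats, 0.60 intergenic, 0.05 in promoters and CpG islands;
CHG 0.014 and CHH 0.011 everywhere), methylated sites have true per-read
level 0.8 (incomplete clonal methylation) and unmethylated sites 0.0
(complete conversion). A flat per-site level was rejected deliberately:
with rare contexts vastly outnumbering CG sites, a uniform low CHH level
plus the ≥ 1-read methylated-site rule would mislabel a large share of CHH
sites as methylated at 30× and produce context shares unlike any real
methylome. With the bimodal model the expected shares, computable directly
from the baseline table and genome composition, are ≈ 91.4% / 1.8% / 6.8%
mCG/mCHG/mCHH — these defaults were fixed from that calculation, and the
measured shares land within the bands reported for real molluscan WGBS
(≈ 90–93% mCG). Background states are drawn once and shared by all groups
(the groups are the same genomes), so a no-DMR study is a true null in
which between-group differences are read-sampling only.

Inside a planted DMR every site of the DMR's context gets a flat
group-specific level, making the region's pooled Rm equal the planted
value by construction. Planted intervals sit on the caller's 1 kb grid
with ≥ 2 kb separation so each is individually scorable and distinct
plants are never merged into one call. Downstream-flank sequence uses the
intergenic baseline (no distinct downstream methylation class), and repeat
intervals are annotation only — their sequence composition is not
specially modelled.

What the generator does **not** emulate: correlated methylation between
neighbouring sites, coverage biases (GC, mappability), bisulfite
non-conversion noise in the WGBS tables (only the BSP simulator models
conversion failure), partially methylated domains, and real repeat or
island sequence families. Passing tests therefore demonstrate the
correctness of the statistics and the machinery on data satisfying the
stated model, not performance on any real library.

## Numerical choices and degenerate inputs

* Fisher/hypergeometric tails are computed in log space and renormalised
  over the support; a zero margin gives P = 1 by convention.
* Undefined levels (no coverage) propagate as None/NaN and fail window
  eligibility rather than being coerced.
* Ties and orderings are deterministic everywhere: calls sort by
  (chrom, pos), enrichment by (p, term_id), clones by id, merging is
  left-to-right with restart; all generators run from
  `numpy.random.default_rng` seeded from the config.
* Seeds below 2^31 are used throughout; derived streams come from
  `SeedSequence` spawning, so adding a group never perturbs another
  group's draws.

## Scale

The default study (1 Mb, two groups, ~360 k covered sites each) runs the
full pipeline in well under a minute on one CPU; the sizes were chosen so
the whole test suite, including the end-to-end recovery and calibration
checks, stays fast while every filter still engages on realistic counts.
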