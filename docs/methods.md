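# Methods

## Overview

`dgftools` implements a digital genomic footprinting (DGF) analysis: given a
genome sequence, per-cell-type DNase I footprint tracks, TF motif matrices
and a per-base conservation track, it predicts where a transcription factor
is bound, then characterises the predicted sites with a set of interval
statistics. The pipeline has three filtering steps and four downstream
analyses:

1. **Motif scanning.** Both strands of the genome are scanned with one or
   more position probability matrices using MATCH-style scoring (below).
2. **DNase support.** A motif hit counts as occupied in a cell type when at
   least 90% of the motif span is covered by a single DNase I footprint
   (threshold `overlap_threshold = 0.9`, compared with `>=`).
3. **Conservation.** Hits whose information-content-weighted conservation
   score falls below 0.22 are discarded (`conservation_threshold`, kept at
   exactly 0.22).

Downstream: genomic-category distribution and TSS profiles; coverage curves
of regulated genes with a random-gene control; Monte Carlo overlap
enrichment with a normalised ratio and BH-FDR correction; a co-regulatory
factor screen with four selection thresholds; and cross-cell common
footprints with a random-panel control.

All coordinates are 0-based half-open throughout (BED convention); gene
tables in a 1-based dialect are converted on input. Midpoints of even-length
intervals take the lower central coordinate (integer floor division) —
deterministic, and consistent everywhere.

## Motif model and MATCH-style score

A motif of length L stores per-position probabilities p(i, b) derived from
counts with a pseudocount of 1% of the column total, spread evenly over the
four bases (probabilities are therefore invariant under positive rescaling
of the counts). Per-column information content assumes a uniform background:

    IC(i) = 2 + sum_b p(i,b) log2 p(i,b)     (bits, 0 for uniform, 2 for fixed)

A window w is scored by the IC-weighted sum Current = sum_i IC(i) p(i, w_i),
min–max normalised over all sequences so the consensus scores 1 and the
anti-consensus 0:

    score = (Current − Min) / (Max − Min)

The core score is computed identically over the k = 5 consecutive columns of
maximal summed IC (leftmost on ties). A hit requires core score >= 0.75 AND
matrix score >= 0.80; these are documented fallbacks for synthetic runs —
profile-specific cutoffs should be supplied per matrix when scanning real
genomes. Windows containing non-ACGT characters are skipped. Reverse-strand
hits are found by scanning with the reverse-complemented matrix and are
reported on forward-strand coordinates.

For minus-strand hits, the conservation weighting reverses the IC vector so
that column i weights the base it actually matched — the only
self-consistent reading. An all-uniform motif (total IC 0) falls back to an
unweighted mean with a warning.

The package ships a synthetic MRE-like matrix (consensus `TAACGGTT` around
the core PyAACG/TG) for simulations; it is synthetic and clearly labelled as
such, because the classic licensed matrices cannot be redistributed. Any
TRANSFAC- or JASPAR-format matrix file can be supplied instead.

## Enrichment statistics

For a case set of n footprints drawn from a pool of N DNase I footprints
(control = the remaining m = N − n) and a query interval set, we count
footprint **midpoints** falling in the (merged) query: X among the case, Y
among the control. Effect size is the normalised ratio

    r = (X/n) / (Y/m)

with r > 1 meaning enrichment. The test statistic is T = X − Y. Because
X + Y = K is fixed across case-sized resamples of the pool, T = 2X − K is a
monotone function of X, and drawing n footprints without replacement makes X
exactly Hypergeometric(N, K, n). Each Monte Carlo repetition therefore draws
X from that distribution directly — distributionally identical to resampling
footprint indices, at O(repetitions) instead of O(repetitions × N). The
default is 10000 repetitions and the add-one estimator

    p = (1 + #{T_sim at least as extreme}) / (repetitions + 1)

so p is never zero. Direction (positive = enrichment) is reported from r.

The `alternative` parameter selects the tail: `auto` (default) tests in the
direction of the observed deviation, matching how signed findings are
reported; `greater`/`less` fix the direction; `two-sided` doubles the
smaller tail. Note that the direction-adaptive `auto` p-value is effectively
a two-tailed procedure at twice the nominal level — under a symmetric null
P(p < 0.05) is about 0.10, not 0.05. Calibration experiments (and the null
calibration acceptance check) therefore use a fixed-direction test, under
which p is uniform up to the discreteness of the overlap count; the
calibration benchmark uses pools of 4000 footprints with case size 1600 and
~400 query windows so the attainable significance levels lie close to the
nominal 0.05.

BH-FDR adjustment (step-up, clipped at 1) is applied over all tests of a
screen, or per cell type for the per-cell category analyses (configurable
grouping). The hypergeometric expectation nK/N is provided for
expected-overlap reference curves.

## Co-regulator screen

Footprints within ±5 kb (midpoint-to-TSS) of knockdown-regulated genes are
partitioned by the regulation direction of the *closest* regulated gene
(ties broken deterministically toward the lower gene id). Each candidate
factor's peak set is tested against both partitions (same Monte Carlo test;
the pool is the full DNase footprint population). A factor is selected when
all four thresholds hold:

1. FDR-adjusted p < 0.05 for the partition with the larger ratio (the set
   the factor would join — the adjusted-p scope is configurable);
2. max(r_pos, r_neg) > 1.05;
3. at least 20 distinct regulated genes (summed over both directions,
   configurable to per-set) have a footprint whose midpoint lies in the
   factor's peaks;
4. |r_pos − r_neg| > 0.5.

Selected factors join the positive or negative set according to the larger
ratio. The within-set distance to the top factor is 10·(a − b), where a is
the set's highest ratio and b the factor's; 10^(a−b) is available as a
config alternative since the source formula's typography admits both
readings. The linear form anchors the top factor at 0 and is the default.

## Cross-cell comparison

Footprints are reduced to 25-base windows: midpoint ± 12 bp (expanding a
point by 12 bp on each side gives 2·12 + 1 bases), clipped at the chromosome
start. Two footprints are the same site when their windows share >= 6 bp.
The common set across a panel is computed by iterative filtering from the
first (reference) cell type — each step drops reference windows with no
qualifying overlap in the next cell — producing the stepwise retained-count
curve; membership is provably order-insensitive in the non-reference cells.
Counts and coordinates are reported from the reference side to avoid double
counting asymmetric overlaps. Validation against ChIP-seq peaks uses the
expanded windows and a >= 1 bp overlap rule. The random-panel control
resamples per-cell footprints without replacement and reruns the filter.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale; defaults (chosen once as the study conditions for all tests and
benchmarks):

| parameter | default | meaning |
|---|---|---|
| genome_length | 1 Mb | i.i.d. nucleotides, single synthetic chromosome |
| gc_fraction | 0.41 | human-like base composition |
| n_sites | 500 | planted consensus motif instances, non-overlapping, strands Bernoulli(1/2) |
| occupancy_prob | 0.8 | per-cell Bernoulli occupancy of each planted site |
| footprint_sensitivity | 0.95 | probability an occupied site gets a covering DNase footprint |
| background_footprints_per_kb | 1.0 | Poisson background footprint rate (widths 10–30 bp) |
| conservation means | 0.8 / 0.1 | Beta-distributed per-base scores at planted / background bases, concentration 10 |
| n_genes | 200 | non-overlapping genes, 1–4 kb, 2–5 exons, terminal 3'UTR |
| regulated_fraction | 0.1 | round(fraction × n_genes) regulated genes, direction Bernoulli(1/2) |
| regulated_near_site_enrichment | 0.9 | probability a regulated gene is drawn from genes within 10 kb of a planted site |

Emitted footprints at occupied sites cover >= 90% of the site by
construction (inward jitter bounded by floor(0.1·L), outward jitter up to
10 bp), so the generator's sensitivity parameter is the recall ceiling of
the caller. One master seed drives everything through a named per-component
derivation (component name → CRC32 → numpy `SeedSequence` child), so each
component is independently regenerable and the full simulate → call →
annotate → enrich chain is bit-reproducible.

What the generator does *not* emulate: DNase cleavage sequence bias,
footprint-width dependence on the bound factor, correlated occupancy across
cell types, alignment artefacts, and hg19-scale genome structure
(repeats, CpG islands, chromatin domains). Passing recovery benchmarks on
these data therefore demonstrates the correctness of the filtering and
statistics, not expected performance on real genomes.

## Benchmark experiments and measurement conventions

- **Footprint recovery** (default simulation): calls are matched to planted
  occupied sites by >= 50% overlap, the usual convention for footprint
  benchmarks. Exact-coordinate matching would count a hit shifted by one
  base at a planted site — inevitable when a motif is partially
  self-complementary — as both a false positive and a miss, which measures
  bookkeeping rather than detection. Typical operating point at default
  thresholds: recall ≈ 0.94 (sensitivity 0.95 × a small conservation loss),
  precision ≈ 0.99.
- **Co-regulator screen recovery**: 100 independent simulated screens
  (1 cell type, 30% of genes regulated so the >= 20-gene threshold is
  attainable, factor co-localization 0.5 at positively regulated genes vs
  0.05 background; Monte Carlo at 2000 repetitions per test inside the
  replicated screens).
- **Random-panel control**: six cells, 1000 footprints sampled per cell from
  independent pools of 2000 over 1 Mb; the final common count is zero in
  essentially every repetition (the expected count is ~1e-4).
- **Null calibration**: 200 independent case/pool/query triples with the
  query placed independently of the case labels; the rejection rate at
  0.05 must lie within the 95% binomial interval around 0.05.

## Numerical choices and degenerate inputs

- Threshold comparisons are `>=` on both filters (the discard rule is
  stated for the "below cutoff" side only; the closed boundary is applied
  uniformly).
- Overlap support uses the single best footprint, not the union
  (configurable `overlap_mode="union"`), since a hit straddling two
  adjacent footprints is weak evidence of a single protected site.
- Identical intervals hit by several motifs collapse to one footprint
  keeping the best-scoring motif id.
- Conservation lookups default to 0.0 on uncovered bases (configurable) so
  unscored bases can never lift a site over the cutoff; overlapping
  conservation records with conflicting values are an input error.
- r is +inf when Y = 0 with X > 0 (infinite enrichment) and NaN when
  X = Y = 0 (degenerate; such tests report p = 1 and a degenerate flag).
- Chromosome names are matched by exact string equality — no "chr" prefix
  normalisation — so mismatched inputs fail loudly instead of silently
  producing empty overlaps.
- Promoter windows are clipped at coordinate 0; genes at the chromosome
  edge keep truncated promoters.

## Known limitations

- Genome-scale results from the original hg19 analyses (absolute footprint
  counts, category percentages, ChIP validation fractions) require the
  external data sets and are out of scope; the package reproduces the
  *procedures* and validates them on synthetic data.
- The MATCH cutoff pairs shipped as fallbacks are not the published
  profile-specific values, which are not freely redistributable.
- The Monte Carlo null resamples uniformly from the footprint pool; no
  GC- or length-matched sampling is provided.
- De novo motif discovery and GO-term enrichment are external tools; the
  package only exports their inputs (FASTA of kept footprints, midpoint
  windows).
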