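# dgftools

Digital genomic footprinting (DGF) analysis: predict where a transcription
factor binds by intersecting motif matches with DNase I footprints and
evolutionary conservation, then characterise the predicted sites with
interval enrichment statistics.

## Who this is for

Deep DNase I cleavage data reveals short nuclease-protected segments
("footprints") wherever a protein occludes the DNA. Which factor sits in a
given footprint is inferred from the sequence: a footprint over a strong
motif match for factor F, at a position conserved across mammals, is a
strong candidate F binding site — no antibody or ChIP required. `dgftools`
is for regulatory-genomics analysts who have per-cell-type footprint calls
(BED), a genome (FASTA), motif count matrices (TRANSFAC/JASPAR) and a
conservation track (bedGraph/WIG), and want reproducible, testable footprint
predictions plus the standard downstream questions: where do the sites fall
relative to genes, which chromatin factors co-localise with them, and which
sites are shared across cell types.

## The method

**Site prediction.** Both genome strands are scanned with position
probability matrices using the MATCH score — the information-content (IC)
weighted probability sum, min–max normalised so consensus = 1,
anti-consensus = 0 — with separate core (5 highest-IC consecutive columns)
and full-matrix cutoffs. A hit is *occupied* in a cell type when a single
DNase footprint covers ≥ 90% of it, and *conserved* when its IC-weighted
conservation

    w = Σᵢ IC(i)·c(i) / Σᵢ IC(i)   ≥ 0.22

(c(i) = per-base conservation, e.g. phastCons). Occupied, conserved hits
are the predicted footprints.

**Enrichment.** Overlaps between footprint sets and a query dataset (peaks,
promoters, exons, ...) are counted by footprint midpoints. With X of n case
footprints and Y of m control footprints in the query, the effect size is
the normalised ratio **r = (X/n)/(Y/m)** and significance comes from a Monte
Carlo test: resample case-sized subsets from the DNase footprint pool
(10000 repetitions), test statistic T = X − Y, empirical p with BH-FDR
correction.

**Co-regulator screen.** Footprints within ±5 kb of the TSS of
knockdown-regulated genes are split by regulation direction; each candidate
factor's ChIP-seq peaks are tested against both subsets and selected as a
putative co-regulator only if adjusted p < 0.05, ratio > 1.05, ≥ 20
regulated genes are involved, and the two ratios differ by > 0.5.

**Cross-cell comparison.** Footprint midpoints ± 12 bp (25-base windows)
are intersected across cell types with a ≥ 6 bp overlap rule, giving the
common-footprint core and per-step gain/loss counts, with a random-footprint
negative control.

A synthetic-data module generates a full workspace (genome with planted
motif instances, per-cell footprints, conservation, genes, regulated-gene
lists, peak sets) with ground truth, so the entire pipeline is testable
offline. See `docs/methods.md` for model details and design choices.

## Worked example

```sh
dgf simulate --workspace demo --seed 1 --cells 3 --genome-length 500000 \
    --sites 250 --genes 100
dgf run --workspace demo --seed 1
```

This writes a synthetic 500 kb genome with 250 planted motif instances and
runs scan → call → annotate → enrich → coreg → common. Inspect the per-cell
calling summary:

```sh
$ cat demo/output/call_summary.tsv
cell   total_motifs  motifs_overlapping_footprints  overlap_percent  footprint_count
cell1  7005          469                            6.7              381
cell2  7005          472                            6.74             383
cell3  7005          446                            6.37             364
```

7005 motif hits were found genome-wide; 469 (6.7%) of them are covered
≥ 90% by a cell1 DNase footprint, and 381 distinct intervals survive the
conservation filter — the predicted footprints for cell1 (the overlap
percentage is far higher than on a real genome because a quarter of this
synthetic genome's motif hits are planted true sites). `output/` also holds
the audit table of every candidate (overlap fraction, weighted conservation,
kept/discarded), category tallies, TSS profiles, coverage curves with the
random-gene control, the enrichment table (X, Y, n, m, r, p, adjusted p),
the co-regulator screen and the cross-cell common set with its stepwise
retained counts and random control. Library usage mirrors the CLI:

```python
from dgftools import (SimulationParams, simulate_dataset, scan_genome,
                      call_footprints, AnalysisConfig, evaluate_calls)

ds = simulate_dataset(SimulationParams(seed=1))
hits = scan_genome(ds.genome, [ds.motif])
calls, audit = call_footprints(hits, ds.footprints["cell1"], ds.conservation,
                               AnalysisConfig(), motifs={ds.motif.motif_id: ds.motif})
print(evaluate_calls(calls, ds.truth, "cell1"))
# {'n_true': 409, 'n_called': 747, 'recovered': 383, 'tp_calls': 738,
#  'recall': 0.936..., 'precision': 0.987...}
```

At the default study conditions (footprint sensitivity 0.95, conservation
0.8 at planted vs 0.1 at background bases) the caller recovers ~94% of
occupied planted sites with ~99% precision at the default 0.9/0.22
thresholds.

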