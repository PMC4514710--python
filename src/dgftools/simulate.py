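"""Synthetic data with the statistical structure the pipeline assumes.

One master seed drives everything through a named per-component seed
derivation (component name -> CRC32 -> numpy SeedSequence child), so each
component can be regenerated independently yet reproducibly.

The generator emulates, at desk scale, the inputs of a digital genomic
footprinting study: a random genome with planted motif instances, per-cell
DNase I footprint tracks (high sensitivity at occupied sites plus Poisson
background), a conservation track elevated at planted sites, gene models
with a knockdown-regulated subset placed preferentially near planted sites,
and ChIP-seq-like peak sets with tunable co-localization. Defaults are a
1 Mb genome, 500 planted sites, 200 genes and 6 cell types.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .conservation import ConservationTrack
from .coreg import RegulatedGene
from .genes import GeneModel
from .intervals import GenomicInterval, IntervalSet
from .motifs import MotifModel, reverse_complement, synthetic_mre_motif


def rng_for(seed: int, component: str, extra: int = 0) -> np.random.Generator:
    """Deterministic per-component generator derived from the master seed."""
    code = zlib.crc32(component.encode())
    return np.random.default_rng(np.random.SeedSequence((int(seed), code, int(extra))))


@dataclass
class FactorSpec:
    """Co-localization profile of one simulated ChIP-seq factor.

    ``prob_pos``/``prob_neg``/``prob_other`` are the probabilities that a
    planted site near a positively / negatively regulated TSS / elsewhere
    receives a peak over its midpoint.
    """

    name: str
    prob_pos: float = 0.05
    prob_neg: float = 0.05
    prob_other: float = 0.05
    peak_halfwidth: int = 100
    background_per_mb: float = 50.0


@dataclass
class SimulationParams:
    genome_length: int = 1_000_000
    chrom: str = "chrSim"
    gc_fraction: float = 0.41
    n_sites: int = 500
    cell_types: Tuple[str, ...] = ("cell1", "cell2", "cell3", "cell4", "cell5", "cell6")
    occupancy_prob: float = 0.8
    footprint_sensitivity: float = 0.95
    background_footprints_per_kb: float = 1.0
    footprint_width_min: int = 10
    footprint_width_max: int = 30
    footprint_jitter: int = 10
    conservation_planted_mean: float = 0.8
    conservation_background_mean: float = 0.1
    conservation_concentration: float = 10.0
    n_genes: int = 200
    gene_length_min: int = 1000
    gene_length_max: int = 4000
    regulated_fraction: float = 0.1
    direction_split: float = 0.5
    regulated_near_site_enrichment: float = 0.9
    enrichment_window: int = 10_000
    factors: Tuple[FactorSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "occupancy_prob", "footprint_sensitivity",
                     "conservation_planted_mean", "conservation_background_mean",
                     "regulated_fraction", "direction_split",
                     "regulated_near_site_enrichment"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.genome_length < 10 * self.footprint_width_max:
            raise ValueError("genome too short for the footprint width distribution")
        if len(self.cell_types) < 1:
            raise ValueError("at least one cell type required")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset; round-trips through TSV files."""

    sites: pd.DataFrame            # chrom,start,end,strand,motif_id + occ_<cell> columns
    regulated: List[RegulatedGene]
    factor_coloc: pd.DataFrame     # factor, site_index, colocalized

    def to_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        self.sites.to_csv(os.path.join(path, "sites.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [{"gene_id": r.gene_id, "direction": r.direction, "rank": r.rank} for r in self.regulated]
        ).to_csv(os.path.join(path, "regulated.tsv"), sep="\t", index=False)
        self.factor_coloc.to_csv(os.path.join(path, "factor_coloc.tsv"), sep="\t", index=False)

    @classmethod
    def from_dir(cls, path: str) -> "SimulationTruth":
        sites = pd.read_csv(os.path.join(path, "sites.tsv"), sep="\t")
        reg_df = pd.read_csv(os.path.join(path, "regulated.tsv"), sep="\t")
        regulated = [
            RegulatedGene(str(r.gene_id), str(r.direction), float(r.rank))
            for r in reg_df.itertuples()
        ] if len(reg_df) else []
        coloc = pd.read_csv(os.path.join(path, "factor_coloc.tsv"), sep="\t")
        return cls(sites=sites, regulated=regulated, factor_coloc=coloc)

    def occupied_sites(self, cell: str) -> pd.DataFrame:
        return self.sites[self.sites[f"occ_{cell}"] == 1]


# ---------------------------------------------------------------------------
# genome and planted sites

def simulate_genome(params: SimulationParams, rng: Optional[np.random.Generator] = None) -> Dict[str, str]:
    """i.i.d. nucleotide sequence at the configured GC fraction."""
    if params.genome_length < 100:
        raise ValueError("genome_length must be >= 100")
    rng = rng if rng is not None else rng_for(params.seed, "genome")
    gc = params.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=params.genome_length, p=p)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    return {params.chrom: seq}


def plant_sites(
    genome: Dict[str, str],
    motif: MotifModel,
    n_sites: int,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    sample_from_pwm: bool = False,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Write n non-overlapping motif instances into the genome at uniform
    positions, strands Bernoulli(1/2); returns the modified genome and the
    truth table of planted coordinates."""
    rng = rng if rng is not None else rng_for(params.seed, "plant")
    chrom = params.chrom
    seq = bytearray(genome[chrom], "ascii")
    L = motif.length
    glen = len(seq)
    if n_sites * L * 4 > glen:
        raise ValueError("too many sites for this genome length")
    occupied = np.zeros(glen, dtype=bool)
    rows = []
    attempts = 0
    while len(rows) < n_sites:
        attempts += 1
        if attempts > 50 * max(n_sites, 1):
            raise RuntimeError("could not place sites without overlap")
        pos = int(rng.integers(0, glen - L + 1))
        if occupied[pos : pos + L].any():
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        if sample_from_pwm:
            bases = "".join("ACGT"[int(rng.choice(4, p=motif.probs[i]))] for i in range(L))
        else:
            bases = motif.consensus()
        if strand == "-":
            bases = reverse_complement(bases)
        seq[pos : pos + L] = bases.encode("ascii")
        occupied[max(0, pos - L) : pos + 2 * L] = True  # keep planted sites non-adjacent
        rows.append((chrom, pos, pos + L, strand, motif.motif_id))
    sites = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "motif_id"])
    sites = sites.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    out = dict(genome)
    out[chrom] = seq.decode("ascii")
    return out, sites


def simulate_occupancy(
    sites: pd.DataFrame, params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Add a Bernoulli occupancy indicator column per cell type."""
    rng = rng if rng is not None else rng_for(params.seed, "occupancy")
    out = sites.copy()
    for cell in params.cell_types:
        out[f"occ_{cell}"] = (rng.random(len(out)) < params.occupancy_prob).astype(int)
    return out


# ---------------------------------------------------------------------------
# per-cell DNase footprints

def simulate_footprints(
    truth: SimulationTruth,
    params: SimulationParams,
    cell: str,
    rng: Optional[np.random.Generator] = None,
) -> IntervalSet:
    """DNase footprint track for one cell: with probability = sensitivity a
    footprint covering >= 90% of each occupied site (jittered edges), plus
    Poisson background footprints."""
    rng = rng if rng is not None else rng_for(params.seed, f"footprints:{cell}")
    intervals: List[GenomicInterval] = []
    occ = truth.occupied_sites(cell)
    jit = params.footprint_jitter
    for row in occ.itertuples():
        if rng.random() >= params.footprint_sensitivity:
            continue
        L = row.end - row.start
        inward = int(rng.integers(0, L // 10 + 1))  # eats <= 10% of the site
        left_in = inward if rng.random() < 0.5 else 0
        right_in = inward - left_in
        start = max(0, row.start + left_in - int(rng.integers(0, jit + 1)))
        end = row.end - right_in + int(rng.integers(0, jit + 1))
        intervals.append(GenomicInterval(row.chrom, start, max(start + 1, end)))
    n_bg = rng.poisson(params.background_footprints_per_kb * params.genome_length / 1000.0)
    widths = rng.integers(params.footprint_width_min, params.footprint_width_max + 1, size=n_bg)
    starts = rng.integers(0, params.genome_length - params.footprint_width_max, size=n_bg)
    for s, w in zip(starts, widths):
        intervals.append(GenomicInterval(params.chrom, int(s), int(s + w)))
    return IntervalSet(intervals, label=cell)


# ---------------------------------------------------------------------------
# conservation

def _beta_draw(rng: np.random.Generator, mean: float, concentration: float, size: int) -> np.ndarray:
    if concentration <= 0:
        return np.full(size, mean)
    a = mean * concentration
    b = (1.0 - mean) * concentration
    if a <= 0:
        return np.zeros(size)
    if b <= 0:
        return np.ones(size)
    return rng.beta(a, b, size=size)


def simulate_conservation(
    truth: SimulationTruth,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> ConservationTrack:
    """Per-base Beta-distributed scores: elevated mean over planted bases,
    background mean elsewhere."""
    if not (0 <= params.conservation_background_mean <= 1
            and 0 <= params.conservation_planted_mean <= 1):
        raise ValueError("conservation means must lie in [0, 1]")
    rng = rng if rng is not None else rng_for(params.seed, "conservation")
    vals = _beta_draw(rng, params.conservation_background_mean,
                      params.conservation_concentration, params.genome_length)
    for row in truth.sites.itertuples():
        vals[row.start:row.end] = _beta_draw(
            rng, params.conservation_planted_mean, params.conservation_concentration,
            row.end - row.start,
        )
    return ConservationTrack.from_dense({params.chrom: vals})


# ---------------------------------------------------------------------------
# genes and the regulated list

def simulate_annotation_and_genes(
    params: SimulationParams,
    sites: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[GeneModel], List[RegulatedGene]]:
    """Non-overlapping gene models with exon/intron structure and a regulated
    subset placed preferentially near planted sites."""
    rng = rng if rng is not None else rng_for(params.seed, "genes")
    n = params.n_genes
    lengths = rng.integers(params.gene_length_min, params.gene_length_max + 1, size=n)
    free = params.genome_length - int(lengths.sum())
    if free < 0:
        raise ValueError("genes do not fit in the genome (infeasible packing)")
    cuts = np.sort(rng.integers(0, free + 1, size=n))
    starts = cuts + np.concatenate(([0], np.cumsum(lengths[:-1])))
    genes: List[GeneModel] = []
    for i in range(n):
        start, glen = int(starts[i]), int(lengths[i])
        end = start + glen
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(2, 6))
        m = 2 * n_ex - 1
        w = rng.random(m) + 0.1
        seg = np.maximum(1, np.floor(w / w.sum() * (glen - m)).astype(int) + 1)
        seg[-1] += glen - int(seg.sum())
        bounds = start + np.concatenate(([0], np.cumsum(seg)))
        exons = tuple((int(bounds[j]), int(bounds[j + 1])) for j in range(0, m, 2))
        if strand == "+":
            s, e = exons[-1]
            u = max(1, int(0.3 * (e - s)))
            utr3 = ((e - u, e),)
        else:
            s, e = exons[0]
            u = max(1, int(0.3 * (e - s)))
            utr3 = ((s, s + u),)
        genes.append(GeneModel(f"gene{i:04d}", params.chrom, strand, start, end,
                               exons=exons, utr3=utr3))

    n_reg = int(round(params.regulated_fraction * n))
    mids = ((sites["start"] + sites["end"]) // 2).to_numpy() if len(sites) else np.empty(0, int)
    near, far = [], []
    for g in genes:
        if mids.size and np.min(np.abs(np.where(
                mids < g.start, g.start - mids,
                np.where(mids >= g.end, mids - (g.end - 1), 0)))) <= params.enrichment_window:
            near.append(g.gene_id)
        else:
            far.append(g.gene_id)
    rng.shuffle(near)
    rng.shuffle(far)
    chosen: List[str] = []
    for _ in range(n_reg):
        use_near = (rng.random() < params.regulated_near_site_enrichment and near) or not far
        pool = near if (use_near and near) else far
        chosen.append(pool.pop())
    regulated = [
        RegulatedGene(gid, "positive" if rng.random() < params.direction_split else "negative",
                      rank=float(i + 1))
        for i, gid in enumerate(sorted(chosen))
    ]
    return genes, regulated


# ---------------------------------------------------------------------------
# factor peaks

def classify_sites_by_regulated_gene(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    regulated: Sequence[RegulatedGene],
    window: int = 5000,
) -> np.ndarray:
    """Per-site label: direction of the closest regulated TSS within the
    window ("positive"/"negative"), else "none"."""
    by_id = {g.gene_id: g for g in genes}
    entries = sorted(
        ((by_id[r.gene_id].chrom, by_id[r.gene_id].tss, r.gene_id, r.direction) for r in regulated),
        key=lambda t: t[2],
    )
    labels = []
    for row in sites.itertuples():
        mid = (row.start + row.end) // 2
        best = None
        for chrom, tss, gid, direction in entries:
            if chrom != row.chrom:
                continue
            d = abs(mid - tss)
            if best is None or (d, gid) < (best[0], best[1]):
                best = (d, gid, direction)
        labels.append(best[2] if best is not None and best[0] <= window else "none")
    return np.asarray(labels)


def simulate_peaks(
    truth: SimulationTruth,
    params: SimulationParams,
    factor: FactorSpec,
    site_labels: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[IntervalSet, pd.DataFrame]:
    """ChIP-seq-like peaks for one factor: a peak over a planted site's
    midpoint with the class-specific probability, plus Poisson background
    peaks. Returns the peaks and the per-site co-localization truth."""
    rng = rng if rng is not None else rng_for(params.seed, f"peaks:{factor.name}")
    probs = {"positive": factor.prob_pos, "negative": factor.prob_neg, "none": factor.prob_other}
    intervals: List[GenomicInterval] = []
    rows = []
    for i, row in enumerate(truth.sites.itertuples()):
        hit = rng.random() < probs[str(site_labels[i])]
        rows.append((factor.name, i, int(hit)))
        if hit:
            mid = (row.start + row.end) // 2
            intervals.append(GenomicInterval(
                row.chrom, max(0, mid - factor.peak_halfwidth), mid + factor.peak_halfwidth,
                name=factor.name))
    n_bg = rng.poisson(factor.background_per_mb * params.genome_length / 1e6)
    w = 2 * factor.peak_halfwidth
    starts = rng.integers(0, max(1, params.genome_length - w), size=n_bg)
    for s in starts:
        intervals.append(GenomicInterval(params.chrom, int(s), int(s) + w, name=factor.name))
    coloc = pd.DataFrame(rows, columns=["factor", "site_index", "colocalized"])
    return IntervalSet(intervals, label=factor.name), coloc


# ---------------------------------------------------------------------------
# whole datasets and on-disk workspaces

@dataclass
class SimulatedDataset:
    params: SimulationParams
    motif: MotifModel
    genome: Dict[str, str]
    truth: SimulationTruth
    footprints: Dict[str, IntervalSet]
    conservation: ConservationTrack
    genes: List[GeneModel]
    regulated: List[RegulatedGene]
    factor_peaks: Dict[str, IntervalSet]


def simulate_dataset(params: SimulationParams, motif: Optional[MotifModel] = None) -> SimulatedDataset:
    """Generate every pipeline input from one master seed."""
    motif = motif or synthetic_mre_motif()
    genome = simulate_genome(params)
    genome, sites = plant_sites(genome, motif, params.n_sites, params)
    sites = simulate_occupancy(sites, params)
    truth = SimulationTruth(sites=sites, regulated=[], factor_coloc=pd.DataFrame(
        columns=["factor", "site_index", "colocalized"]))
    footprints = {cell: simulate_footprints(truth, params, cell) for cell in params.cell_types}
    conservation = simulate_conservation(truth, params)
    genes, regulated = simulate_annotation_and_genes(params, sites)
    truth.regulated = regulated
    labels = classify_sites_by_regulated_gene(sites, genes, regulated, window=5000)
    factor_peaks: Dict[str, IntervalSet] = {}
    coloc_frames = []
    for spec in params.factors:
        peaks, coloc = simulate_peaks(truth, params, spec, labels)
        factor_peaks[spec.name] = peaks
        coloc_frames.append(coloc)
    if coloc_frames:
        truth.factor_coloc = pd.concat(coloc_frames, ignore_index=True)
    return SimulatedDataset(params, motif, genome, truth, footprints, conservation,
                            genes, regulated, factor_peaks)


def simulate_workspace(params: SimulationParams, outdir: str,
                       motif: Optional[MotifModel] = None) -> SimulatedDataset:
    """Materialise a full simulated workspace directory in the on-disk
    formats the pipeline reads, plus the ground-truth tables."""
    from . import io as dio

    ds = simulate_dataset(params, motif)
    os.makedirs(outdir, exist_ok=True)
    dio.write_fasta(ds.genome, os.path.join(outdir, "genome.fa"))
    for cell, fps in ds.footprints.items():
        dio.write_bed(fps, os.path.join(outdir, f"footprints_{cell}.bed"),
                      params={"cell": cell})
    dio.write_bedgraph(ds.conservation, os.path.join(outdir, "conservation.bedgraph"))
    dio.write_gene_table(ds.genes, os.path.join(outdir, "genes.tsv"))
    dio.write_regulated_genes(
        ((r.gene_id, r.direction, r.rank) for r in ds.regulated),
        os.path.join(outdir, "regulated_genes.tsv"))
    manifest = []
    for name, peaks in ds.factor_peaks.items():
        bed = f"peaks_{name}.bed"
        dio.write_bed(peaks, os.path.join(outdir, bed), params={"factor": name})
        manifest.append((name, bed))
    dio.write_peak_manifest(manifest, os.path.join(outdir, "peak_manifest.tsv"))
    ds.truth.to_dir(os.path.join(outdir, "truth"))
    return ds


def evaluate_calls(calls, truth: SimulationTruth, cell: str,
                   min_overlap_frac: float = 0.5) -> dict:
    """Recall/precision of called footprints against occupied planted sites.

    Matching is by overlap, the usual convention for footprint benchmarks: a
    planted occupied site is recovered when some call covers at least
    ``min_overlap_frac`` of it, and a call is a true positive when an
    occupied site covers that fraction of the call. Overlapping hits shifted
    by a base or two (inevitable with a partially self-complementary motif)
    thus count as detections of the same site, while calls on unplanted
    sequence or unoccupied sites count against precision.
    """
    occ = truth.occupied_sites(cell)
    sites = [(row.chrom, row.start, row.end) for row in occ.itertuples()]
    preds = [(c.chrom, c.start, c.end) for c in calls]

    def covered(a, b, frac_of):
        if a[0] != b[0]:
            return False
        ov = min(a[2], b[2]) - max(a[1], b[1])
        return ov >= frac_of * (a[2] - a[1]) if ov > 0 else False

    by_chrom: Dict[str, List[Tuple[str, int, int]]] = {}
    for p in preds:
        by_chrom.setdefault(p[0], []).append(p)
    site_by_chrom: Dict[str, List[Tuple[str, int, int]]] = {}
    for s in sites:
        site_by_chrom.setdefault(s[0], []).append(s)

    recovered = sum(
        1 for s in sites
        if any(covered(s, p, min_overlap_frac) for p in by_chrom.get(s[0], ()))
    )
    true_pos = sum(
        1 for p in preds
        if any(covered(p, s, min_overlap_frac) for s in site_by_chrom.get(p[0], ()))
    )
    return {
        "n_true": len(sites),
        "n_called": len(preds),
        "recovered": recovered,
        "tp_calls": true_pos,
        "recall": recovered / len(sites) if sites else float("nan"),
        "precision": true_pos / len(preds) if preds else float("nan"),
    }
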