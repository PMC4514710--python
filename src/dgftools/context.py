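"""Genomic context of predicted footprints: category assignment, TSS
profiles, and distance-to-gene coverage curves with a random-gene control.

Sites are represented by their midpoints throughout. A site falling in more
than one annotation category is assigned by the fixed priority promoter >
exon > 3'UTR > intron > intergenic, evaluated across all genes, so gene
input order can never change an assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .genes import GeneModel

CATEGORIES = ("promoter", "exon", "3utr", "intron", "intergenic")


@dataclass(frozen=True)
class CategoryAssignment:
    midpoint: Tuple[str, int]
    category: str
    gene_id: str = ""


def _category_index(genes: Sequence[GeneModel], config: AnalysisConfig):
    """Per-chromosome interval lists (start, end, gene_id) for each category."""
    index: Dict[str, Dict[str, List[Tuple[int, int, str]]]] = {c: {} for c in CATEGORIES[:4]}
    for g in genes:
        ps, pe = g.promoter(config.promoter_upstream, config.promoter_downstream)
        index["promoter"].setdefault(g.chrom, []).append((ps, pe, g.gene_id))
        for s, e in g.exons:
            index["exon"].setdefault(g.chrom, []).append((s, e, g.gene_id))
        for s, e in g.utr3:
            index["3utr"].setdefault(g.chrom, []).append((s, e, g.gene_id))
        index["intron"].setdefault(g.chrom, []).append((g.start, g.end, g.gene_id))
    out = {}
    for cat, per_chrom in index.items():
        out[cat] = {
            chrom: (
                np.asarray([r[0] for r in sorted(recs)]),
                np.asarray([r[1] for r in sorted(recs)]),
                [r[2] for r in sorted(recs)],
            )
            for chrom, recs in per_chrom.items()
        }
    return out


def _containing_gene(pos: int, chrom_index) -> Optional[str]:
    if chrom_index is None:
        return None
    starts, ends, ids = chrom_index
    mask = (starts <= pos) & (pos < ends)
    if not mask.any():
        return None
    # deterministic: lexicographically lowest gene id among containers
    return min(ids[i] for i in np.flatnonzero(mask))


def assign_category(
    site: Tuple[str, int],
    genes: Sequence[GeneModel],
    config: Optional[AnalysisConfig] = None,
    _index=None,
) -> CategoryAssignment:
    """Assign one site midpoint to its highest-priority category."""
    config = config or AnalysisConfig()
    index = _index if _index is not None else _category_index(genes, config)
    chrom, pos = site
    for cat in CATEGORIES[:4]:
        gid = _containing_gene(pos, index[cat].get(chrom))
        if gid is not None:
            return CategoryAssignment(site, cat, gid)
    return CategoryAssignment(site, "intergenic", "")


def assign_categories(
    sites: Iterable[Tuple[str, int]],
    genes: Sequence[GeneModel],
    config: Optional[AnalysisConfig] = None,
) -> List[CategoryAssignment]:
    config = config or AnalysisConfig()
    index = _category_index(genes, config)
    return [assign_category(s, genes, config, _index=index) for s in sites]


def category_counts(assignments: Sequence[CategoryAssignment]) -> Dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    return counts


@dataclass
class TssProfile:
    """Counts of site midpoints in signed, strand-oriented bins around TSSs."""

    bin_width: int
    window: int
    counts: Dict[int, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def as_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        bins = np.arange(-self.window, self.window, self.bin_width)
        return bins, np.asarray([self.counts.get(int(b), 0) for b in bins])


def tss_profile(
    sites: Sequence[Tuple[str, int]],
    genes: Sequence[GeneModel],
    config: Optional[AnalysisConfig] = None,
) -> TssProfile:
    """Histogram of site midpoints around every TSS, oriented so negative
    offsets are upstream of the gene. A site near several TSSs counts once
    per TSS."""
    config = config or AnalysisConfig()
    bw, window = config.tss_bin_width, config.tss_window
    prof = TssProfile(bin_width=bw, window=window)
    by_chrom: Dict[str, List[int]] = {}
    for chrom, pos in sites:
        by_chrom.setdefault(chrom, []).append(pos)
    arr = {c: np.asarray(sorted(p)) for c, p in by_chrom.items()}
    for g in genes:
        pts = arr.get(g.chrom)
        if pts is None:
            continue
        offsets = pts - g.tss if g.strand == "+" else g.tss - pts
        sel = offsets[(offsets >= -window) & (offsets < window)]
        for off in sel:
            b = int(np.floor(off / bw) * bw)
            prof.counts[b] = prof.counts.get(b, 0) + 1
    return prof


def gene_distance(site: Tuple[str, int], gene: GeneModel) -> float:
    """bp distance from a site midpoint to the gene body; 0 inside, inf on
    another chromosome."""
    chrom, pos = site
    if chrom != gene.chrom:
        return float("inf")
    return float(gene.distance_to(pos))


@dataclass
class CoverageCurve:
    """Fraction of genes with a site within each distance of the gene body."""

    distances: np.ndarray
    fractions: np.ndarray
    label: str = ""
    genes_used: int = 0


DEFAULT_DISTANCE_GRID = tuple(range(0, 100_001, 10_000))


def coverage_curve(
    sites: Sequence[Tuple[str, int]],
    gene_ids: Sequence[str],
    genes: Sequence[GeneModel],
    distance_grid: Sequence[int] = DEFAULT_DISTANCE_GRID,
    label: str = "",
) -> CoverageCurve:
    """For each distance d, the fraction of listed genes whose nearest site
    midpoint is within d bp of the gene body (0 = inside)."""
    by_id = {g.gene_id: g for g in genes}
    resolved = []
    missing = 0
    for gid in gene_ids:
        if gid in by_id:
            resolved.append(by_id[gid])
        else:
            missing += 1
    if missing:
        warnings.warn(f"{missing} gene ids not found in annotation; excluded")
    by_chrom: Dict[str, np.ndarray] = {}
    tmp: Dict[str, List[int]] = {}
    for chrom, pos in sites:
        tmp.setdefault(chrom, []).append(pos)
    by_chrom = {c: np.asarray(sorted(p)) for c, p in tmp.items()}

    min_dists = []
    for g in resolved:
        pts = by_chrom.get(g.chrom)
        if pts is None or pts.size == 0:
            min_dists.append(float("inf"))
            continue
        d = np.where(
            pts < g.start, g.start - pts,
            np.where(pts >= g.end, pts - (g.end - 1), 0),
        )
        min_dists.append(float(d.min()))
    md = np.asarray(min_dists) if min_dists else np.empty(0)
    grid = np.asarray(list(distance_grid), dtype=float)
    if len(resolved) == 0:
        fractions = np.zeros(grid.size)
    else:
        fractions = np.asarray([(md <= d).mean() for d in grid])
    return CoverageCurve(grid, fractions, label=label, genes_used=len(resolved))


def random_gene_control(
    sites: Sequence[Tuple[str, int]],
    genes: Sequence[GeneModel],
    sample_size: int = 100,
    repetitions: int = 10,
    seed: int = 0,
    distance_grid: Sequence[int] = DEFAULT_DISTANCE_GRID,
) -> CoverageCurve:
    """Average coverage curve over ``repetitions`` uniform random gene samples
    (without replacement), the negative control for the regulated-gene curve."""
    if len(genes) < sample_size:
        raise ValueError(f"annotation has {len(genes)} genes, need >= {sample_size}")
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in genes]
    curves = []
    for _ in range(repetitions):
        chosen = rng.choice(len(ids), size=sample_size, replace=False)
        cc = coverage_curve(sites, [ids[i] for i in chosen], genes, distance_grid)
        curves.append(cc.fractions)
    mean = np.mean(np.vstack(curves), axis=0)
    return CoverageCurve(np.asarray(list(distance_grid), dtype=float), mean,
                         label=f"random-{sample_size}x{repetitions}", genes_used=sample_size)
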