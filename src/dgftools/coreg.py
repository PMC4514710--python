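"""Co-regulatory factor screen.

Footprints within a window of the TSS of knockdown-regulated genes are
partitioned by the regulation direction of their closest regulated gene.
Each candidate factor's ChIP-seq peak set is then tested for enrichment
against both partitions; a factor is selected as a putative co-regulator
when all four thresholds hold (adjusted p < alpha, max ratio > 1.05,
>= 20 distinct regulated genes with peak-overlapped footprints, and a ratio
difference > 0.5 between the two partitions), and joins the positive or
negative set according to its larger ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .genes import GeneModel
from .intervals import GenomicInterval, IntervalSet, points_in_set
from .stats import EnrichmentResult, adjust_results, monte_carlo_test


@dataclass(frozen=True)
class RegulatedGene:
    gene_id: str
    direction: str  # "positive" (down upon knockdown) or "negative"
    rank: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"direction must be positive/negative, got {self.direction!r}")


@dataclass
class FactorScreenResult:
    factor: str
    r_pos: float
    r_neg: float
    p_pos: float
    p_neg: float
    p_adj_pos: Optional[float] = None
    p_adj_neg: Optional[float] = None
    gene_count: int = 0
    selected: bool = False
    assigned_set: str = "none"   # positive | negative | none
    distance: float = float("nan")


def footprints_near_regulated_tss(
    footprints: IntervalSet,
    regulated: Sequence[RegulatedGene],
    genes: Sequence[GeneModel],
    window: int = 5000,
) -> Tuple[IntervalSet, IntervalSet]:
    """Partition footprints near regulated TSSs by regulation direction.

    Each footprint is assigned to its closest regulated gene by
    midpoint-to-TSS distance (ties broken by lower gene id) and kept iff
    that distance is <= ``window``. The returned intervals carry the
    assigned gene id in their ``name`` field.
    """
    if not regulated:
        raise ValueError("no regulated genes supplied")
    by_id = {g.gene_id: g for g in genes}
    reg_sorted = sorted(regulated, key=lambda r: r.gene_id)
    tss_by_chrom: Dict[str, List[Tuple[int, str, str]]] = {}
    for r in reg_sorted:
        g = by_id.get(r.gene_id)
        if g is None:
            raise ValueError(f"regulated gene {r.gene_id} not in annotation")
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, r.gene_id, r.direction))

    pos, neg = [], []
    for iv in footprints:
        entries = tss_by_chrom.get(iv.chrom)
        if not entries:
            continue
        mid = iv.midpoint
        # closest TSS; ties resolved by the (already sorted) lower gene id
        best = min(entries, key=lambda t: (abs(mid - t[0]), t[1]))
        if abs(mid - best[0]) > window:
            continue
        tagged = GenomicInterval(iv.chrom, iv.start, iv.end, strand=iv.strand,
                                 name=best[1], score=iv.score)
        (pos if best[2] == "positive" else neg).append(tagged)
    return (IntervalSet(pos, label="positive-gene footprints"),
            IntervalSet(neg, label="negative-gene footprints"))


def _count_genes_with_peak_overlap(subset: IntervalSet, peaks: IntervalSet) -> set:
    """Distinct regulated gene ids with >= 1 footprint midpoint inside a peak."""
    genes = set()
    inside = points_in_set(subset.midpoints(), peaks)
    arrays = subset.chrom_arrays()
    for chrom, mask in inside.items():
        _, _, idx = arrays[chrom]
        for i in np.flatnonzero(mask):
            gid = subset[int(idx[i])].name
            if gid:
                genes.add(gid)
    return genes


def apply_selection(
    r_pos: float,
    r_neg: float,
    p_adj_pos: float,
    p_adj_neg: float,
    gene_count: int,
    config: Optional[AnalysisConfig] = None,
) -> Tuple[bool, str]:
    """Evaluate the four selection thresholds; returns (selected, assigned set).

    The adjusted-p threshold applies to the partition with the larger ratio
    (the set the factor would join).
    """
    config = config or AnalysisConfig()
    rp = r_pos if not np.isnan(r_pos) else -np.inf
    rn = r_neg if not np.isnan(r_neg) else -np.inf
    pos_is_larger = rp >= rn
    best_r = max(rp, rn)
    p_best = p_adj_pos if pos_is_larger else p_adj_neg
    diff = abs(rp - rn) if np.isfinite(rp) and np.isfinite(rn) else np.inf
    ok = (
        p_best < config.fdr_alpha
        and best_r > config.ratio_threshold
        and gene_count >= config.min_gene_count
        and diff > config.ratio_diff_threshold
    )
    if not ok:
        return False, "none"
    return True, ("positive" if pos_is_larger else "negative")


def screen_factor(
    factor: str,
    peaks: IntervalSet,
    pos_footprints: IntervalSet,
    neg_footprints: IntervalSet,
    pool: IntervalSet,
    config: Optional[AnalysisConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> FactorScreenResult:
    """Raw (un-adjusted) screen of one factor: enrichment against both
    direction partitions plus the qualifying-gene count. Selection is applied
    after FDR adjustment across the whole screen (see :func:`screen_factors`).
    """
    config = config or AnalysisConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if len(peaks) == 0 or len(pos_footprints) == 0 or len(neg_footprints) == 0:
        return FactorScreenResult(factor, float("nan"), float("nan"), 1.0, 1.0, gene_count=0)
    res_pos = monte_carlo_test(pos_footprints, pool, peaks,
                               repetitions=config.mc_repetitions, rng=rng,
                               alternative=config.mc_alternative)
    res_neg = monte_carlo_test(neg_footprints, pool, peaks,
                               repetitions=config.mc_repetitions, rng=rng,
                               alternative=config.mc_alternative)
    if config.gene_count_scope == "combined":
        genes = (_count_genes_with_peak_overlap(pos_footprints, peaks)
                 | _count_genes_with_peak_overlap(neg_footprints, peaks))
        gene_count = len(genes)
    else:
        gene_count = min(
            len(_count_genes_with_peak_overlap(pos_footprints, peaks)),
            len(_count_genes_with_peak_overlap(neg_footprints, peaks)),
        )
    return FactorScreenResult(
        factor=factor,
        r_pos=res_pos.ratio,
        r_neg=res_neg.ratio,
        p_pos=res_pos.p_value,
        p_neg=res_neg.p_value,
        gene_count=gene_count,
    )


def factor_distance(a: float, b: float, formula: str = "linear") -> float:
    """Distance of a factor (ratio b) from the set's top factor (ratio a).

    "linear": 10*(a - b); "power": 10**(a - b). Zero for the top factor,
    strictly increasing as b decreases.
    """
    if not (a >= b > 0):
        raise ValueError("need a >= b > 0")
    if formula == "linear":
        return 10.0 * (a - b)
    if formula == "power":
        return 10.0 ** (a - b)
    raise ValueError(f"unknown distance formula {formula!r}")


def screen_factors(
    factor_peaks: Dict[str, IntervalSet],
    pos_footprints: IntervalSet,
    neg_footprints: IntervalSet,
    pool: IntervalSet,
    config: Optional[AnalysisConfig] = None,
    seed: Optional[int] = None,
) -> List[FactorScreenResult]:
    """Screen every factor, BH-adjust all tests as one family, apply the four
    thresholds, assign sets and compute within-set distances to the top factor."""
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    results = [
        screen_factor(name, peaks, pos_footprints, neg_footprints, pool, config, rng)
        for name, peaks in sorted(factor_peaks.items())
    ]
    # one FDR family across all tests of the screen
    flat = []
    for res in results:
        flat.append(res.p_pos)
        flat.append(res.p_neg)
    from .stats import bh_fdr

    adjusted = bh_fdr(flat)
    for i, res in enumerate(results):
        res.p_adj_pos = adjusted[2 * i]
        res.p_adj_neg = adjusted[2 * i + 1]
        if np.isnan(res.r_pos) and np.isnan(res.r_neg):
            res.selected, res.assigned_set = False, "none"
            continue
        res.selected, res.assigned_set = apply_selection(
            res.r_pos, res.r_neg, res.p_adj_pos, res.p_adj_neg, res.gene_count, config
        )
    for set_name in ("positive", "negative"):
        members = [r for r in results if r.assigned_set == set_name]
        if not members:
            continue
        ratios = [r.r_pos if set_name == "positive" else r.r_neg for r in members]
        a = max(x for x in ratios if np.isfinite(x)) if any(np.isfinite(x) for x in ratios) else float("nan")
        for r, b in zip(members, ratios):
            if np.isfinite(a) and np.isfinite(b) and a >= b > 0:
                r.distance = factor_distance(a, b, config.distance_formula)
    return results


def results_table(results: Sequence[FactorScreenResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "factor": r.factor, "r_pos": r.r_pos, "r_neg": r.r_neg,
                "p_pos": r.p_pos, "p_neg": r.p_neg,
                "p_adj_pos": r.p_adj_pos, "p_adj_neg": r.p_adj_neg,
                "gene_count": r.gene_count, "selected": r.selected,
                "assigned_set": r.assigned_set, "distance": r.distance,
            }
            for r in results
        ]
    )
    if not df.empty:
        df = df.sort_values(["assigned_set", "distance", "factor"]).reset_index(drop=True)
    return df
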