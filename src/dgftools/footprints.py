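"""Footprint calling: DNase support plus conservation filtering of motif hits.

A motif hit becomes a predicted TF footprint in a cell type when (a) at
least 90% of the motif span is covered by a single DNase I footprint in that
cell type and (b) its information-content-weighted conservation score is at
least 0.22 (both thresholds configurable, both compared with >=).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .conservation import ConservationTrack
from .intervals import GenomicInterval, IntervalSet
from .motifs import MotifHit, MotifModel


@dataclass(frozen=True)
class TFFootprint:
    """A conserved, DNase-supported motif instance (the pipeline's end product)."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_id: str
    cell_type: str
    conservation: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, strand=self.strand,
                               name=self.motif_id, score=self.conservation)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def overlap_fraction(hit: GenomicInterval, footprints: IntervalSet, mode: str = "single") -> float:
    """Fraction of ``hit`` covered by DNase footprints, in [0, 1].

    Default "single" mode takes the best *individual* footprint (a hit
    straddling two adjacent footprints does not get credit for their union);
    "union" mode counts every covered base once.
    """
    arrays = footprints.chrom_arrays().get(hit.chrom)
    if arrays is None:
        return 0.0
    starts, ends, _ = arrays
    if mode == "single":
        ov = np.minimum(ends, hit.end) - np.maximum(starts, hit.start)
        best = int(ov.max(initial=0))
        return max(best, 0) / hit.length
    if mode == "union":
        lo = np.maximum(starts, hit.start)
        hi = np.minimum(ends, hit.end)
        keep = hi > lo
        if not keep.any():
            return 0.0
        segs = sorted(zip(lo[keep].tolist(), hi[keep].tolist()))
        covered, cur_lo, cur_hi = 0, *segs[0]
        for s, e in segs[1:]:
            if s > cur_hi:
                covered += cur_hi - cur_lo
                cur_lo, cur_hi = s, e
            else:
                cur_hi = max(cur_hi, e)
        covered += cur_hi - cur_lo
        return covered / hit.length
    raise ValueError(f"unknown overlap mode {mode!r}")


def weighted_conservation(hit: MotifHit, motif: MotifModel, track: ConservationTrack) -> float:
    """IC-weighted mean conservation across the hit, in [0, 1].

    Column i of the motif weights the base it actually matched, so for a
    minus-strand hit the IC vector is reversed against genome coordinates.
    An all-uniform motif (total IC = 0) falls back to the unweighted mean,
    with a warning.
    """
    if hit.length != motif.length:
        raise ValueError("hit length != motif length")
    cons = track.values(hit.chrom, hit.start, hit.end)
    ic = motif.ic[::-1] if hit.strand == "-" else motif.ic
    total = float(ic.sum())
    if total <= 0:
        warnings.warn("motif has zero total information content; using unweighted mean")
        return float(cons.mean())
    return float((ic * cons).sum() / total)


def call_footprints(
    hits: Sequence[MotifHit],
    footprints: IntervalSet,
    track: ConservationTrack,
    config: Optional[AnalysisConfig] = None,
    motifs: Optional[Dict[str, MotifModel]] = None,
    cell_type: str = "",
) -> Tuple[List[TFFootprint], pd.DataFrame]:
    """Filter motif hits into predicted footprints for one cell type.

    Returns the kept footprints (sorted, identical intervals from different
    motifs collapsed to the highest matrix-scoring one) and an audit table
    listing every candidate with its overlap fraction, conservation score
    and keep/discard outcome.
    """
    config = config or AnalysisConfig()
    if motifs is None:
        raise ValueError("motifs mapping (motif_id -> MotifModel) is required")
    if len(footprints) == 0:
        warnings.warn("empty DNase footprint set: no footprints can be called")
    cell = cell_type or footprints.label

    rows = []
    kept: Dict[Tuple[str, int, int], Tuple[float, TFFootprint]] = {}
    for h in hits:
        motif = motifs[h.motif_id]
        f = overlap_fraction(h.interval, footprints, mode=config.overlap_mode)
        w = weighted_conservation(h, motif, track)
        keep = f >= config.overlap_threshold and w >= config.conservation_threshold
        rows.append((h.chrom, h.start, h.end, h.strand, h.motif_id,
                     h.matrix_score, f, w, keep))
        if keep:
            key = (h.chrom, h.start, h.end)
            prev = kept.get(key)
            if prev is None or h.matrix_score > prev[0]:
                kept[key] = (
                    h.matrix_score,
                    TFFootprint(h.chrom, h.start, h.end, h.strand, h.motif_id, cell, w),
                )
    audit = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "motif", "match_score",
                 "overlap_fraction", "weighted_conservation", "kept"],
    )
    calls = sorted((fp for _, fp in kept.values()), key=lambda f: (f.chrom, f.start, f.end))
    return calls, audit


def summarize_callset(
    hits: Sequence[MotifHit],
    footprints: IntervalSet,
    calls: Sequence[TFFootprint],
    config: Optional[AnalysisConfig] = None,
) -> dict:
    """Per-cell summary: total motifs, DNase-supported motifs, their
    percentage (2 decimals) and the final footprint count."""
    config = config or AnalysisConfig()
    total = len(hits)
    if total == 0:
        raise ValueError("no motif hits to summarise")
    supported = sum(
        1 for h in hits
        if overlap_fraction(h.interval, footprints, mode=config.overlap_mode)
        >= config.overlap_threshold
    )
    return {
        "total_motifs": total,
        "motifs_overlapping_footprints": supported,
        "overlap_percent": percentage(supported, total),
        "footprint_count": len(calls),
    }


def percentage(part: int, total: int, decimals: int = 2) -> float:
    """``part`` as a percentage of ``total``, rounded to ``decimals`` places."""
    if total == 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, decimals)


def footprints_to_intervalset(calls: Iterable[TFFootprint], label: str = "") -> IntervalSet:
    return IntervalSet((fp.interval for fp in calls), label=label)


def supporting_footprints(
    calls: Sequence[TFFootprint],
    footprints: IntervalSet,
    label: str = "",
) -> IntervalSet:
    """The DNase footprints that carry the called sites.

    For each call, the single best-overlapping DNase footprint is taken;
    duplicates (two calls inside one footprint) collapse to one member. The
    result is a subset of ``footprints`` and is the case set for the
    resampling enrichment tests, whose pool is the full DNase footprint
    population.
    """
    chosen = set()
    for fp in calls:
        arrays = footprints.chrom_arrays().get(fp.chrom)
        if arrays is None:
            continue
        starts, ends, idx = arrays
        ov = np.minimum(ends, fp.end) - np.maximum(starts, fp.start)
        best = int(ov.argmax())
        if ov[best] > 0:
            chosen.add(int(idx[best]))
    return IntervalSet((footprints[i] for i in sorted(chosen)), label=label or footprints.label)


def write_audit(audit: pd.DataFrame, path: str) -> None:
    audit.to_csv(path, sep="\t", index=False)


def export_fasta(calls: Sequence[TFFootprint], sequences: Dict[str, str], path: str) -> None:
    """Write kept footprint sequences (strand-oriented) for external motif tools."""
    from .io import write_fasta
    from .motifs import reverse_complement

    out = {}
    for i, fp in enumerate(calls):
        seq = sequences[fp.chrom][fp.start:fp.end]
        if fp.strand == "-":
            seq = reverse_complement(seq)
        out[f"{fp.cell_type or 'fp'}_{i}_{fp.chrom}_{fp.start}_{fp.end}"] = seq
    write_fasta(out, path)
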