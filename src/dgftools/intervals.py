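"""Genomic interval data model.

All coordinates are 0-based half-open (BED convention) throughout the
package; readers of 1-based dialects convert on input. Intervals are the
universal currency here: DNase I footprints, motif hits, ChIP-seq peaks,
promoter windows and expanded midpoint windows are all ``GenomicInterval``
objects collected in sorted ``IntervalSet`` containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named sequence.

    ``strand`` is "+", "-" or "." (unstranded); ``name`` and ``score`` are
    optional annotation carried through BED round-trips.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 on different chroms)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def midpoint(iv: GenomicInterval) -> int:
    """Midpoint coordinate, floor((start+end)/2); always inside [start, end)."""
    return iv.midpoint


class IntervalSet:
    """An immutable, sorted collection of :class:`GenomicInterval`.

    Sorted by (chrom, start, end); duplicates are kept and counted
    distinctly. Per-chromosome numpy coordinate arrays are cached for the
    vectorised overlap operations used throughout the pipeline.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = "") -> None:
        self.label = label
        self.intervals: List[GenomicInterval] = sorted(intervals, key=GenomicInterval.sort_key)
        self._arrays: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(label={self.label!r}, n={len(self)})"

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def chrom_arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, index-into-self) arrays, start-sorted."""
        if self._arrays is None:
            arrays: Dict[str, List[List[int]]] = {}
            for i, iv in enumerate(self.intervals):
                rec = arrays.setdefault(iv.chrom, [[], [], []])
                rec[0].append(iv.start)
                rec[1].append(iv.end)
                rec[2].append(i)
            self._arrays = {
                c: (np.asarray(s), np.asarray(e), np.asarray(idx))
                for c, (s, e, idx) in arrays.items()
            }
        return self._arrays

    def midpoints(self) -> Dict[str, np.ndarray]:
        """Per-chromosome midpoint coordinate arrays (same order as chrom_arrays)."""
        return {
            c: (s + e) // 2 for c, (s, e, _) in self.chrom_arrays().items()
        }

    def with_label(self, label: str) -> "IntervalSet":
        return IntervalSet(self.intervals, label=label)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals as a minimal sorted list of disjoint intervals."""
    merged: List[GenomicInterval] = []
    for iv in sorted(intervals, key=GenomicInterval.sort_key):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def max_overlap_bp(iv: GenomicInterval, ivset: IntervalSet) -> int:
    """Largest single-interval overlap (bp) between ``iv`` and any member of ``ivset``."""
    arrays = ivset.chrom_arrays().get(iv.chrom)
    if arrays is None:
        return 0
    starts, ends, _ = arrays
    ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
    best = int(ov.max(initial=0))
    return max(best, 0)


def count_overlapping(iv: GenomicInterval, ivset: IntervalSet, min_bp: int = 1) -> int:
    """Number of members of ``ivset`` overlapping ``iv`` by at least ``min_bp`` bases."""
    arrays = ivset.chrom_arrays().get(iv.chrom)
    if arrays is None:
        return 0
    starts, ends, _ = arrays
    ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
    return int((ov >= min_bp).sum())


def points_in_set(points_by_chrom: Dict[str, np.ndarray], ivset: IntervalSet) -> Dict[str, np.ndarray]:
    """Boolean membership of point coordinates in the union of ``ivset``.

    Intervals are merged first, so overlapping query intervals never double
    count. Returns one boolean array per chromosome, aligned with the input
    point arrays.
    """
    merged = merge_intervals(ivset.intervals)
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    tmp: Dict[str, List[List[int]]] = {}
    for iv in merged:
        rec = tmp.setdefault(iv.chrom, [[], []])
        rec[0].append(iv.start)
        rec[1].append(iv.end)
    starts_ends = {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in tmp.items()}
    out: Dict[str, np.ndarray] = {}
    for chrom, pts in points_by_chrom.items():
        pts = np.asarray(pts)
        if chrom not in starts_ends or pts.size == 0:
            out[chrom] = np.zeros(pts.shape, dtype=bool)
            continue
        starts, ends = starts_ends[chrom]
        idx = np.searchsorted(starts, pts, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(pts.shape, dtype=bool)
        inside[ok] = pts[ok] < ends[idx[ok]]
        out[chrom] = inside
    return out
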