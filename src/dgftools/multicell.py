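"""Cross-cell-type footprint comparison.

Footprints are reduced to 25-bp windows (midpoint plus 12 bp on each side)
and two footprints are considered the same site when their windows share at
least 6 bp. The common set across a panel of cell types is built by
iterative filtering from a reference cell type, reproducing the stepwise
retained-count curve; a random-footprint control documents that independent
panels share essentially nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, IntervalSet


@dataclass
class CellFootprintPanel:
    """Ordered (cell type, footprint set) pairs; the first cell is the reference."""

    cells: List[Tuple[str, IntervalSet]]

    def __post_init__(self) -> None:
        if len(self.cells) < 2:
            raise ValueError("panel needs at least two cell types")

    @property
    def labels(self) -> List[str]:
        return [c for c, _ in self.cells]


def expand_midpoint(iv: GenomicInterval, flank: int = 12) -> GenomicInterval:
    """(2*flank + 1)-base window centred on the midpoint, clipped at 0."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    mid = iv.midpoint
    return GenomicInterval(iv.chrom, max(0, mid - flank), mid + flank + 1,
                           strand=iv.strand, name=iv.name, score=iv.score)


def expand_set(ivset: IntervalSet, flank: int = 12) -> IntervalSet:
    return IntervalSet((expand_midpoint(iv, flank) for iv in ivset), label=ivset.label)


def _overlaps_any(iv: GenomicInterval, other: IntervalSet, min_bp: int) -> bool:
    arrays = other.chrom_arrays().get(iv.chrom)
    if arrays is None:
        return False
    starts, ends, _ = arrays
    ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
    return bool((ov >= min_bp).any())


def common_footprints(
    panel: CellFootprintPanel,
    min_overlap: int = 6,
    flank: int = 12,
) -> Tuple[IntervalSet, List[Tuple[str, int]]]:
    """Reference-cell windows present in every cell type of the panel.

    All footprints are expanded to midpoint windows first; a reference
    window survives a step iff some window of that cell type overlaps it by
    >= ``min_overlap`` bp. Returns the retained reference windows and the
    stepwise (cell, retained count) curve, starting with the reference's
    own input count. Membership is order-insensitive in the non-reference
    cells; only the reported coordinates follow the reference.
    """
    window_len = 2 * flank + 1
    if min_overlap > window_len:
        raise ValueError(f"min_overlap {min_overlap} exceeds window length {window_len}")
    ref_label, ref_set = panel.cells[0]
    current = list(expand_set(ref_set, flank))
    steps: List[Tuple[str, int]] = [(ref_label, len(current))]
    for label, other in panel.cells[1:]:
        expanded = expand_set(other, flank)
        current = [iv for iv in current if _overlaps_any(iv, expanded, min_overlap)]
        steps.append((label, len(current)))
    return IntervalSet(current, label=f"common:{ref_label}"), steps


def specific_footprints(
    reference: IntervalSet,
    comparison: IntervalSet,
    min_overlap: int = 6,
    flank: int = 12,
) -> Tuple[IntervalSet, IntervalSet, IntervalSet]:
    """(shared, reference-only, comparison-only) midpoint windows.

    Shared windows are counted and reported from the reference side.
    """
    ref = expand_set(reference, flank)
    cmp_ = expand_set(comparison, flank)
    shared, ref_only = [], []
    for iv in ref:
        (shared if _overlaps_any(iv, cmp_, min_overlap) else ref_only).append(iv)
    cmp_only = [iv for iv in cmp_ if not _overlaps_any(iv, ref, min_overlap)]
    return (
        IntervalSet(shared, label="shared"),
        IntervalSet(ref_only, label="reference-only"),
        IntervalSet(cmp_only, label="comparison-only"),
    )


def random_panel_control(
    dnase_panels: Sequence[Tuple[str, IntervalSet]],
    sample_sizes: Sequence[int],
    repetitions: int = 10,
    seed: int = 0,
    min_overlap: int = 6,
    flank: int = 12,
) -> List[List[Tuple[str, int]]]:
    """Negative control: sample random footprints per cell (without
    replacement) and rerun the common-footprint filter; returns one stepwise
    count curve per repetition."""
    if len(dnase_panels) != len(sample_sizes):
        raise ValueError("one sample size per cell type required")
    for (label, pool), size in zip(dnase_panels, sample_sizes):
        if size > len(pool):
            raise ValueError(f"cannot sample {size} footprints from {len(pool)} in {label}")
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(repetitions):
        cells = []
        for (label, pool), size in zip(dnase_panels, sample_sizes):
            chosen = rng.choice(len(pool), size=size, replace=False)
            cells.append((label, IntervalSet((pool[int(i)] for i in chosen), label=label)))
        _, steps = common_footprints(CellFootprintPanel(cells), min_overlap, flank)
        curves.append(steps)
    return curves


def chip_validation_overlap(
    windows: IntervalSet,
    chip_peaks: IntervalSet,
    min_overlap: int = 1,
) -> float:
    """Fraction of common-footprint windows overlapping a ChIP-seq peak by
    >= ``min_overlap`` bp."""
    if len(windows) == 0:
        raise ValueError("empty window set")
    hit = sum(1 for iv in windows if _overlaps_any(iv, chip_peaks, min_overlap))
    return hit / len(windows)
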