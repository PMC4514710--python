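"""Gene models: TSS, exon structure and 3'UTR for category and distance analyses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

Span = Tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A gene body with exon blocks and optional 3'UTR spans.

    Coordinates are 0-based half-open. The TSS is the transcribed 5' end:
    ``start`` on the + strand, ``end - 1`` on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: Tuple[Span, ...]
    utr3: Tuple[Span, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid body [{self.start}, {self.end})")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: exon list is empty")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s}, {e}) outside body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, upstream: int = 2500, downstream: int = 500) -> Span:
        """Strand-oriented promoter window around the TSS, clipped at 0.

        On the + strand this is [TSS - upstream, TSS + downstream); on the -
        strand the orientation flips. ``downstream`` bases include the TSS base.
        """
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss - downstream + 1, self.tss + upstream + 1
        return (max(0, lo), max(1, hi))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to(self, pos: int) -> int:
        """bp gap from ``pos`` to the gene body; 0 if inside (same-chrom only)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


def exons_from_blocks(start: int, block_sizes: Sequence[int], block_starts: Sequence[int]) -> Tuple[Span, ...]:
    """Expand BED12-style relative blocks into absolute exon spans."""
    if len(block_sizes) != len(block_starts):
        raise ValueError("block size/start lists differ in length")
    return tuple((start + bs, start + bs + sz) for sz, bs in zip(block_sizes, block_starts))
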