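"""TF motif models and MATCH-style genome scanning.

A motif is a position probability matrix with per-column information content
(IC). A window is scored by the IC-weighted sum of the matched-base
probabilities, min-max normalised over all possible sequences so scores lie
in [0, 1] with the consensus at 1 and the anti-consensus at 0. A separate
"core" score is computed over the k consecutive highest-IC columns (k = 5,
the classic MATCH convention), and a hit requires both the core and the full
matrix score to clear their cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import motifs as bio_motifs

from .intervals import GenomicInterval, IntervalSet

BASES = "ACGT"
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

DEFAULT_CORE_LENGTH = 5
DEFAULT_CORE_CUTOFF = 0.75
DEFAULT_MATRIX_CUTOFF = 0.80


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to codes A=0 C=1 G=2 T=3, anything else 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(comp)[::-1]


def information_content(probs: Sequence[float]) -> float:
    """Column IC in bits: 2 + sum(p * log2 p), with 0*log2(0) = 0.

    Assumes a uniform background; a deterministic column scores 2 bits, a
    uniform column 0.
    """
    p = np.asarray(probs, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probabilities")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {p.sum()}, expected 1")
    nz = p[p > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


@dataclass(frozen=True, eq=False)
class MotifModel:
    """Position probability matrix with IC weights and score cutoffs."""

    motif_id: str
    probs: np.ndarray                 # shape (L, 4), rows sum to 1
    core_length: int = DEFAULT_CORE_LENGTH
    core_cutoff: float = DEFAULT_CORE_CUTOFF
    matrix_cutoff: float = DEFAULT_MATRIX_CUTOFF

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must have shape (L, 4)")
        if p.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        if not (0.0 <= self.core_cutoff <= 1.0 and 0.0 <= self.matrix_cutoff <= 1.0):
            raise ValueError("cutoffs must lie in [0, 1]")
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount_fraction: float = 0.01,
        **kwargs,
    ) -> "MotifModel":
        """Build from a count matrix (L, 4), adding a pseudocount of
        ``pseudocount_fraction`` x column total, spread evenly over the four
        bases, before normalising. Probabilities are invariant under any
        positive rescaling of the counts.
        """
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError("counts must have shape (L, 4)")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        totals = c.sum(axis=1, keepdims=True)
        alpha = pseudocount_fraction * totals
        with np.errstate(invalid="ignore"):
            probs = (c + alpha / 4.0) / (totals + alpha)
        probs[totals[:, 0] == 0] = 0.25
        return cls(motif_id=motif_id, probs=probs, **kwargs)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def ic(self) -> np.ndarray:
        """Per-column information content in bits (cached)."""
        cached = getattr(self, "_ic", None)
        if cached is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(self.probs > 0, self.probs * np.log2(self.probs), 0.0)
            cached = 2.0 + plogp.sum(axis=1)
            object.__setattr__(self, "_ic", cached)
        return cached

    @property
    def core_start(self) -> int:
        """Start of the k consecutive columns with maximal summed IC (leftmost tie)."""
        k = min(self.core_length, self.length)
        sums = np.convolve(self.ic, np.ones(k), mode="valid")
        return int(np.argmax(sums))

    @property
    def core_slice(self) -> slice:
        k = min(self.core_length, self.length)
        return slice(self.core_start, self.core_start + k)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmin(axis=1))

    def reverse_complement(self) -> "MotifModel":
        """The same binding model read on the opposite strand."""
        rc_probs = self.probs[::-1, ::-1].copy()
        L = self.length
        k = min(self.core_length, L)
        rc = MotifModel(
            motif_id=self.motif_id,
            probs=rc_probs,
            core_length=self.core_length,
            core_cutoff=self.core_cutoff,
            matrix_cutoff=self.matrix_cutoff,
        )
        # pin the rc core to mirror the forward core, not a re-derived argmax
        object.__setattr__(rc, "_core_start_override", L - self.core_start - k)
        return rc

    def _effective_core_start(self) -> int:
        override = getattr(self, "_core_start_override", None)
        return self.core_start if override is None else int(override)

    def with_cutoffs(self, core_cutoff: float, matrix_cutoff: float) -> "MotifModel":
        return replace(self, core_cutoff=core_cutoff, matrix_cutoff=matrix_cutoff)


@dataclass(frozen=True)
class MotifHit:
    """A scored motif instance; coordinates are always on the forward strand."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_id: str
    matrix_score: float
    core_score: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, strand=self.strand,
                               name=self.motif_id, score=self.matrix_score)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _weighted_bounds(motif: MotifModel, positions: slice) -> Tuple[float, float]:
    ic = motif.ic[positions]
    p = motif.probs[positions]
    return float((ic * p.min(axis=1)).sum()), float((ic * p.max(axis=1)).sum())


def match_score(window: str, motif: MotifModel) -> Tuple[float, float]:
    """(matrix score, core score) of a window against a motif, each in [0, 1].

    score = (Current - Min) / (Max - Min) where Current is the IC-weighted
    sum of matched-base probabilities and Min/Max are its extrema over all
    sequences. Degenerate motifs where Max == Min score 1 by convention.
    """
    if len(window) != motif.length:
        raise ValueError(f"window length {len(window)} != motif length {motif.length}")
    enc = encode_sequence(window)
    if (enc > 3).any():
        raise ValueError("window contains non-ACGT characters")
    idx = np.arange(motif.length)
    current = motif.ic * motif.probs[idx, enc]

    def norm(sl: slice) -> float:
        lo, hi = _weighted_bounds(motif, sl)
        cur = float(current[sl].sum())
        if hi - lo <= 0:
            return 1.0
        return (cur - lo) / (hi - lo)

    cs = motif._effective_core_start()
    k = min(motif.core_length, motif.length)
    return norm(slice(0, motif.length)), norm(slice(cs, cs + k))


def _window_scores(enc: np.ndarray, motif: MotifModel) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised (matrix, core) scores for every window start; NaN where the
    window contains a non-ACGT base."""
    L = motif.length
    n = enc.size - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    weights = np.empty((L, 5))
    weights[:, :4] = motif.ic[:, None] * motif.probs
    weights[:, 4] = np.nan
    current = np.zeros(n)
    cs = motif._effective_core_start()
    k = min(motif.core_length, L)
    core_current = np.zeros(n)
    for i in range(L):
        contrib = weights[i, enc[i : i + n]]
        current += contrib
        if cs <= i < cs + k:
            core_current += contrib
    lo, hi = _weighted_bounds(motif, slice(0, L))
    clo, chi = _weighted_bounds(motif, slice(cs, cs + k))
    with np.errstate(invalid="ignore"):
        matrix = (current - lo) / (hi - lo) if hi > lo else np.ones(n)
        core = (core_current - clo) / (chi - clo) if chi > clo else np.ones(n)
    return matrix, core


def scan_genome(
    sequences: Dict[str, str],
    motifs: Sequence[MotifModel],
) -> List[MotifHit]:
    """Scan both strands of every sequence; emit hits passing each motif's
    core AND matrix cutoffs, on forward-strand coordinates, sorted.

    Windows containing non-ACGT characters are skipped. Reverse-strand hits
    are found by scanning with the reverse-complemented model, so the
    reported interval is the forward-strand span the motif occupies.
    """
    hits: List[MotifHit] = []
    for chrom in sorted(sequences):
        enc = encode_sequence(sequences[chrom])
        for motif in motifs:
            for strand, model in (("+", motif), ("-", motif.reverse_complement())):
                matrix, core = _window_scores(enc, model)
                with np.errstate(invalid="ignore"):
                    keep = (matrix >= motif.matrix_cutoff) & (core >= motif.core_cutoff)
                for pos in np.flatnonzero(keep):
                    hits.append(
                        MotifHit(
                            chrom=chrom,
                            start=int(pos),
                            end=int(pos) + motif.length,
                            strand=strand,
                            motif_id=motif.motif_id,
                            matrix_score=float(matrix[pos]),
                            core_score=float(core[pos]),
                        )
                    )
    hits.sort(key=lambda h: (h.chrom, h.start, h.end, h.strand, h.motif_id))
    return hits


def hits_to_intervalset(hits: Iterable[MotifHit], label: str = "") -> IntervalSet:
    """Hits as BED6-ready intervals (name = motif id, score = matrix score x1000)."""
    return IntervalSet(
        (
            GenomicInterval(h.chrom, h.start, h.end, strand=h.strand,
                            name=h.motif_id, score=float(int(round(h.matrix_score * 1000))))
            for h in hits
        ),
        label=label,
    )


# ---------------------------------------------------------------------------
# Matrix file parsing (TRANSFAC / JASPAR), via Bio.motifs

def _counts_to_array(counts) -> np.ndarray:
    return np.column_stack([np.asarray(counts[b], dtype=float) for b in BASES])


def read_transfac(path: str, **kwargs) -> List[MotifModel]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "TRANSFAC")
    models = []
    for m in parsed:
        motif_id = m.get("AC") or m.get("ID") or m.name or "motif"
        models.append(MotifModel.from_counts(motif_id, _counts_to_array(m.counts), **kwargs))
    return models


def read_jaspar(path: str, **kwargs) -> List[MotifModel]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    models = []
    for m in parsed:
        motif_id = m.matrix_id or m.name or "motif"
        models.append(MotifModel.from_counts(motif_id, _counts_to_array(m.counts), **kwargs))
    return models


def read_motifs(path: str, fmt: str = "transfac", **kwargs) -> List[MotifModel]:
    if fmt.lower() == "transfac":
        return read_transfac(path, **kwargs)
    if fmt.lower() == "jaspar":
        return read_jaspar(path, **kwargs)
    raise ValueError(f"unsupported motif format {fmt!r}")


# Synthetic Myb-recognition-element-like matrix (consensus TAACGGtt around the
# core PyAACG/TG). Stands in for licensed TRANSFAC matrices in simulations and
# tests; any user-supplied matrix file can replace it.
_SYNTHETIC_MRE_COUNTS = np.array(
    [
        [50, 300, 50, 600],   # T/C (pyrimidine)
        [960, 14, 13, 13],    # A
        [960, 13, 14, 13],    # A
        [15, 950, 15, 20],    # C
        [15, 15, 770, 200],   # G/T (K)
        [40, 40, 840, 80],    # G
        [200, 200, 150, 450], # t (weak)
        [250, 200, 150, 400], # t (weak)
    ],
    dtype=float,
)


def synthetic_mre_motif(
    motif_id: str = "MRE_SYN",
    core_cutoff: float = DEFAULT_CORE_CUTOFF,
    matrix_cutoff: float = DEFAULT_MATRIX_CUTOFF,
) -> MotifModel:
    """The package's built-in synthetic MRE-like motif (8 columns)."""
    return MotifModel.from_counts(
        motif_id, _SYNTHETIC_MRE_COUNTS, core_cutoff=core_cutoff, matrix_cutoff=matrix_cutoff
    )
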