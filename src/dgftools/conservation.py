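"""Per-base conservation track (phastCons-like scores in [0, 1]).

The track stores sorted, non-overlapping runs per chromosome; any base not
covered by a run takes a configurable default (0.0 unless overridden), so
unscored bases can never push a site above a conservation cutoff.
"""

from __future__ import annotations

from typing import Dict, Iterable, Tuple

import numpy as np

Record = Tuple[str, int, int, float]


class ConservationTrack:
    def __init__(
        self,
        runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]],
        default: float = 0.0,
    ) -> None:
        """``runs`` maps chrom -> (starts, ends, values), start-sorted and disjoint."""
        self.runs = runs
        self.default = float(default)

    @classmethod
    def from_records(cls, records: Iterable[Record], default: float = 0.0) -> "ConservationTrack":
        """Build a track from (chrom, start, end, value) records.

        Records may abut or duplicate; overlapping records with *different*
        values are an error (ambiguous base score). Values must lie in [0, 1].
        """
        per_chrom: Dict[str, list] = {}
        for chrom, start, end, value in records:
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"conservation value {value} outside [0, 1] at {chrom}:{start}-{end}")
            if start < 0 or end <= start:
                raise ValueError(f"invalid run [{start}, {end}) on {chrom}")
            per_chrom.setdefault(chrom, []).append((start, end, float(value)))
        runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, recs in per_chrom.items():
            recs.sort()
            starts = np.asarray([r[0] for r in recs], dtype=np.int64)
            ends = np.asarray([r[1] for r in recs], dtype=np.int64)
            values = np.asarray([r[2] for r in recs], dtype=float)
            overlap = starts[1:] < ends[:-1]
            if overlap.any():
                bad = np.flatnonzero(overlap & (values[1:] != values[:-1]))
                if bad.size:
                    i = int(bad[0])
                    raise ValueError(
                        f"overlapping conservation records with conflicting values on "
                        f"{chrom} near position {int(starts[i + 1])}"
                    )
                # equal-value overlaps: merge into disjoint runs
                merged = []
                cs, ce, cv = recs[0]
                for s, e, v in recs[1:]:
                    if s < ce and v == cv:
                        ce = max(ce, e)
                    elif s <= ce and v == cv:
                        ce = max(ce, e)
                    else:
                        merged.append((cs, ce, cv))
                        cs, ce, cv = s, e, v
                merged.append((cs, ce, cv))
                starts = np.asarray([r[0] for r in merged], dtype=np.int64)
                ends = np.asarray([r[1] for r in merged], dtype=np.int64)
                values = np.asarray([r[2] for r in merged], dtype=float)
            runs[chrom] = (starts, ends, values)
        return cls(runs, default=default)

    @classmethod
    def from_dense(cls, dense: Dict[str, np.ndarray], default: float = 0.0) -> "ConservationTrack":
        """Build from one value per base (run-length encoded internally)."""
        runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, vals in dense.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
                raise ValueError("dense conservation values outside [0, 1]")
            if vals.size == 0:
                runs[chrom] = (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change)).astype(np.int64)
            ends = np.concatenate((change, [vals.size])).astype(np.int64)
            runs[chrom] = (starts, ends, vals[starts])
        return cls(runs, default=default)

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values(chrom, pos, pos + 1)[0])

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); uncovered bases take the default."""
        n = end - start
        out = np.full(n, self.default, dtype=float)
        rec = self.runs.get(chrom)
        if rec is None:
            return out
        starts, ends, vals = rec
        if starts.size == 0:
            return out
        pos = np.arange(start, end)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        covered = np.zeros(n, dtype=bool)
        covered[ok] = pos[ok] < ends[idx[ok]]
        out[covered] = vals[idx[covered]]
        return out

    def records(self) -> Iterable[Record]:
        """Iterate runs as (chrom, start, end, value), sorted."""
        for chrom in sorted(self.runs):
            starts, ends, vals = self.runs[chrom]
            for s, e, v in zip(starts, ends, vals):
                yield chrom, int(s), int(e), float(v)
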