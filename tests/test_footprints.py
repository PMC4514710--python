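"""DNase-overlap + conservation filtering of motif hits."""

import numpy as np
import pytest

from dgftools.config import AnalysisConfig
from dgftools.conservation import ConservationTrack
from dgftools.footprints import (call_footprints, overlap_fraction, percentage,
                                 summarize_callset, supporting_footprints,
                                 weighted_conservation)
from dgftools.intervals import GenomicInterval, IntervalSet
from dgftools.motifs import MotifHit, MotifModel

from conftest import make_intervals, random_motif


def constant_track(value, chrom="chr1", length=100_000):
    return ConservationTrack.from_dense({chrom: np.full(length, float(value))})


class TestOverlapFraction:
    def test_full_containment(self):
        hit = GenomicInterval("chr1", 100, 110)
        assert overlap_fraction(hit, make_intervals([(90, 120)])) == 1.0

    def test_nine_of_ten_bases(self):
        hit = GenomicInterval("chr1", 100, 110)
        fps = make_intervals([(101, 130)])
        f = overlap_fraction(hit, fps)
        assert f == pytest.approx(0.9)
        assert f >= AnalysisConfig().overlap_threshold  # >= comparison keeps it

    def test_two_adjacent_footprints_not_pooled(self):
        hit = GenomicInterval("chr1", 100, 110)
        fps = make_intervals([(95, 105), (105, 115)])
        assert overlap_fraction(hit, fps, mode="single") == 0.5
        assert overlap_fraction(hit, fps, mode="union") == 1.0

    def test_no_footprints(self):
        hit = GenomicInterval("chr1", 100, 110)
        assert overlap_fraction(hit, IntervalSet([])) == 0.0

    def test_brute_force_oracle_small_instances(self, rng):
        for _ in range(200):
            s = int(rng.integers(0, 480))
            hit = GenomicInterval("chr1", s, s + int(rng.integers(1, 20)))
            coords = []
            for _ in range(int(rng.integers(0, 8))):
                fs = int(rng.integers(0, 490))
                coords.append((fs, fs + int(rng.integers(1, 30))))
            fps = make_intervals(coords)
            best = 0
            for fs, fe in coords:
                best = max(best, sum(1 for p in range(hit.start, hit.end) if fs <= p < fe))
            assert overlap_fraction(hit, fps) == pytest.approx(best / hit.length)


class TestWeightedConservation:
    def test_constant_track_equals_constant(self, rng):
        track = constant_track(0.73)
        for _ in range(10):
            m = random_motif(rng, length=int(rng.integers(4, 10)))
            hit = MotifHit("chr1", 500, 500 + m.length, "+", "RND", 1.0, 1.0)
            assert weighted_conservation(hit, m, track) == pytest.approx(0.73, abs=1e-12)

    def test_hand_summation(self, sharp_motif):
        # IC = (2, 1, 1, 0); conservation (0.9, 0.3, 0.1, 0.6)
        # -> (2*0.9 + 1*0.3 + 1*0.1 + 0*0.6) / 4 = 0.55
        track = ConservationTrack.from_records([
            ("chr1", 100, 101, 0.9), ("chr1", 101, 102, 0.3),
            ("chr1", 102, 103, 0.1), ("chr1", 103, 104, 0.6)])
        hit = MotifHit("chr1", 100, 104, "+", "TEST_IC", 1.0, 1.0)
        assert weighted_conservation(hit, sharp_motif, track) == pytest.approx(0.55)

    def test_minus_strand_reverses_weights(self, sharp_motif):
        track = ConservationTrack.from_records([
            ("chr1", 100, 101, 0.9), ("chr1", 101, 102, 0.3),
            ("chr1", 102, 103, 0.1), ("chr1", 103, 104, 0.6)])
        hit = MotifHit("chr1", 100, 104, "-", "TEST_IC", 1.0, 1.0)
        # weights (0, 1, 1, 2) against (0.9, 0.3, 0.1, 0.6) -> 1.6/4
        assert weighted_conservation(hit, sharp_motif, track) == pytest.approx(0.4)

    def test_equal_ic_gives_arithmetic_mean(self):
        probs = np.tile([0.5, 0.5, 0.0, 0.0], (4, 1))
        m = MotifModel("EQ", probs)
        track = ConservationTrack.from_records([
            ("chr1", 0, 1, 0.2), ("chr1", 1, 2, 0.4),
            ("chr1", 2, 3, 0.6), ("chr1", 3, 4, 0.8)])
        hit = MotifHit("chr1", 0, 4, "+", "EQ", 1.0, 1.0)
        assert weighted_conservation(hit, m, track) == pytest.approx(0.5)

    def test_zero_ic_motif_warns_and_uses_mean(self):
        m = MotifModel("U", np.tile([0.25] * 4, (4, 1)))
        track = constant_track(0.3)
        hit = MotifHit("chr1", 10, 14, "+", "U", 1.0, 1.0)
        with pytest.warns(UserWarning):
            assert weighted_conservation(hit, m, track) == pytest.approx(0.3)


def _mk_hit(start, motif, score=1.0, strand="+"):
    return MotifHit("chr1", start, start + motif.length, strand,
                    motif.motif_id, score, score)


class TestCallFootprints:
    def test_hand_built_fixture(self, sharp_motif):
        """5 hits: 3 covered >= 90% by footprints, of which 2 conserved."""
        m = sharp_motif
        hits = [_mk_hit(s, m) for s in (100, 200, 300, 400, 500)]
        fps = make_intervals([(95, 120), (198, 210), (300, 304), (450, 460)])
        # covered: 100, 200, 300; not covered: 400, 500
        dense = np.full(1000, 0.05)
        dense[100:104] = 0.9   # conserved
        dense[200:204] = 0.9   # conserved
        dense[300:304] = 0.05  # not conserved
        track = ConservationTrack.from_dense({"chr1": dense})
        calls, audit = call_footprints(hits, fps, track, motifs={m.motif_id: m})
        assert [c.start for c in calls] == [100, 200]
        assert len(audit) == 5
        assert audit["kept"].sum() == 2
        assert set(audit.columns) >= {"overlap_fraction", "weighted_conservation", "kept"}

    def test_boundary_conservation_exactly_kept(self, sharp_motif):
        """A site scoring exactly the cutoff is kept (only scores *below* are
        discarded)."""
        m = sharp_motif
        hits = [_mk_hit(100, m)]
        fps = make_intervals([(90, 120)])
        track = constant_track(0.22)
        calls, _ = call_footprints(hits, fps, track, motifs={m.motif_id: m})
        assert len(calls) == 1

    def test_no_dnase_footprints(self, sharp_motif):
        m = sharp_motif
        hits = [_mk_hit(s, m) for s in (100, 200)]
        track = constant_track(1.0)
        with pytest.warns(UserWarning):
            calls, audit = call_footprints(hits, IntervalSet([]), track,
                                           motifs={m.motif_id: m})
        assert calls == []
        assert len(audit) == 2
        assert (audit["overlap_fraction"] == 0).all()

    def test_identical_intervals_collapse_to_best_motif(self, sharp_motif):
        m1 = sharp_motif
        m2 = MotifModel("OTHER", m1.probs)
        hits = [_mk_hit(100, m1, score=0.9), _mk_hit(100, m2, score=0.95)]
        fps = make_intervals([(90, 120)])
        calls, _ = call_footprints(hits, fps, constant_track(0.9),
                                   motifs={"TEST_IC": m1, "OTHER": m2})
        assert len(calls) == 1
        assert calls[0].motif_id == "OTHER"

    def test_threshold_monotonicity(self, sharp_motif, rng):
        """Raising either threshold never increases the number of calls."""
        m = sharp_motif
        hits = [_mk_hit(int(s), m) for s in rng.integers(0, 900, 40) ]
        coords = [(int(s), int(s) + int(rng.integers(2, 12)))
                  for s in rng.integers(0, 950, 30)]
        fps = make_intervals(coords)
        track = ConservationTrack.from_dense({"chr1": rng.random(1200)})
        counts = []
        for ov in (0.3, 0.6, 0.9):
            row = []
            for cons in (0.1, 0.3, 0.5):
                cfg = AnalysisConfig(overlap_threshold=ov, conservation_threshold=cons)
                calls, _ = call_footprints(hits, fps, track, cfg, motifs={m.motif_id: m})
                row.append(len(calls))
            counts.append(row)
        arr = np.array(counts)
        assert (np.diff(arr, axis=0) <= 0).all()
        assert (np.diff(arr, axis=1) <= 0).all()


class TestSummaries:
    def test_percentage_rounding(self):
        assert percentage(2, 1000) == 0.20
        assert percentage(0, 10) == 0.0
        with pytest.raises(ValueError):
            percentage(1, 0)

    def test_summary_counts(self, sharp_motif):
        m = sharp_motif
        hits = [_mk_hit(s, m) for s in (100, 200, 300)]
        fps = make_intervals([(95, 120)])
        calls, _ = call_footprints(hits, fps, constant_track(0.9),
                                   motifs={m.motif_id: m})
        s = summarize_callset(hits, fps, calls)
        assert s["total_motifs"] == 3
        assert s["motifs_overlapping_footprints"] == 1
        assert s["overlap_percent"] == pytest.approx(33.33)
        assert s["motifs_overlapping_footprints"] <= s["total_motifs"]
        assert s["footprint_count"] == 1

    def test_supporting_footprints_subset_and_dedup(self, sharp_motif):
        m = sharp_motif
        fps = make_intervals([(90, 120), (190, 220)])
        hits = [_mk_hit(100, m), _mk_hit(105, m), _mk_hit(200, m)]
        calls, _ = call_footprints(hits, fps, constant_track(0.9),
                                   motifs={m.motif_id: m})
        support = supporting_footprints(calls, fps)
        assert [(iv.start, iv.end) for iv in support] == [(90, 120), (190, 220)]
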