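"""Statistical and determinism contracts of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from dgftools.config import AnalysisConfig
from dgftools.footprints import call_footprints, overlap_fraction
from dgftools.intervals import GenomicInterval
from dgftools.motifs import scan_genome, synthetic_mre_motif
from dgftools.simulate import (FactorSpec, SimulationParams, SimulationTruth,
                               classify_sites_by_regulated_gene, evaluate_calls,
                               plant_sites, simulate_annotation_and_genes,
                               simulate_conservation, simulate_dataset,
                               simulate_footprints, simulate_genome,
                               simulate_occupancy, simulate_peaks)


SMALL = dict(genome_length=120_000, n_sites=60, n_genes=25,
             cell_types=("cell1", "cell2"))


class TestGenome:
    def test_gc_fraction_within_3se(self):
        p = SimulationParams(genome_length=100_000, gc_fraction=0.5, seed=0)
        (seq,) = simulate_genome(p).values()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        se = np.sqrt(0.5 * 0.5 / len(seq))
        assert abs(gc - 0.5) < 3 * se

    def test_same_seed_identical(self):
        p = SimulationParams(genome_length=50_000, seed=3)
        assert simulate_genome(p) == simulate_genome(p)

    def test_gc_zero_is_at_only(self):
        p = SimulationParams(genome_length=10_000, gc_fraction=0.0, seed=1)
        (seq,) = simulate_genome(p).values()
        assert set(seq) <= {"A", "T"}


class TestPlantSites:
    def test_scan_recovers_all_planted(self):
        p = SimulationParams(seed=5, **SMALL)
        m = synthetic_mre_motif()
        genome = simulate_genome(p)
        genome, sites = plant_sites(genome, m, p.n_sites, p)
        hits = {(h.chrom, h.start, h.end, h.strand) for h in scan_genome(genome, [m])}
        for row in sites.itertuples():
            assert (row.chrom, row.start, row.end, row.strand) in hits

    def test_zero_sites_leaves_genome_unchanged(self):
        p = SimulationParams(seed=5, **SMALL)
        genome = simulate_genome(p)
        out, sites = plant_sites(genome, synthetic_mre_motif(), 0, p)
        assert out == genome and len(sites) == 0

    def test_strand_fraction_near_half(self):
        p = SimulationParams(genome_length=2_000_000, n_sites=500, seed=2)
        genome = simulate_genome(p)
        _, sites = plant_sites(genome, synthetic_mre_motif(), 500, p)
        frac = (sites["strand"] == "+").mean()
        se = np.sqrt(0.25 / 500)
        assert abs(frac - 0.5) < 3 * se

    def test_sites_non_overlapping(self):
        p = SimulationParams(seed=5, **SMALL)
        genome = simulate_genome(p)
        _, sites = plant_sites(genome, synthetic_mre_motif(), p.n_sites, p)
        s = sites.sort_values("start")
        assert (s["start"].values[1:] >= s["end"].values[:-1]).all()


class TestFootprints:
    def _truth(self, params, occupancy=1.0):
        m = synthetic_mre_motif()
        genome = simulate_genome(params)
        _, sites = plant_sites(genome, m, params.n_sites, params)
        params2 = params
        if occupancy != params.occupancy_prob:
            params2 = SimulationParams(**{**params.__dict__, "occupancy_prob": occupancy})
        sites = simulate_occupancy(sites, params2)
        return SimulationTruth(sites=sites, regulated=[],
                               factor_coloc=pd.DataFrame(
                                   columns=["factor", "site_index", "colocalized"]))

    def test_full_sensitivity_no_background_covers_occupied_only(self):
        p = SimulationParams(seed=8, footprint_sensitivity=1.0,
                             background_footprints_per_kb=0.0,
                             occupancy_prob=0.7, **SMALL)
        truth = self._truth(p, occupancy=0.7)
        fps = simulate_footprints(truth, p, "cell1")
        occ = truth.occupied_sites("cell1")
        assert len(fps) == len(occ)
        for row in occ.itertuples():
            f = overlap_fraction(GenomicInterval(row.chrom, row.start, row.end), fps)
            assert f >= 0.9

    def test_sensitivity_binomial(self):
        p = SimulationParams(genome_length=2_000_000, n_sites=500, seed=4,
                             occupancy_prob=1.0, footprint_sensitivity=0.95,
                             background_footprints_per_kb=0.0,
                             cell_types=("cell1",))
        truth = self._truth(p)
        fps = simulate_footprints(truth, p, "cell1")
        se = np.sqrt(500 * 0.95 * 0.05)
        assert abs(len(fps) - 475) < 3 * se

    def test_zero_sensitivity_background_only(self):
        p = SimulationParams(seed=8, footprint_sensitivity=0.0, **SMALL)
        truth = self._truth(p)
        fps = simulate_footprints(truth, p, "cell1")
        expected_bg = p.background_footprints_per_kb * p.genome_length / 1000
        assert abs(len(fps) - expected_bg) < 4 * np.sqrt(expected_bg)


class TestConservation:
    def test_planted_mean_elevated(self):
        p = SimulationParams(seed=6, **SMALL)
        m = synthetic_mre_motif()
        genome = simulate_genome(p)
        _, sites = plant_sites(genome, m, p.n_sites, p)
        truth = SimulationTruth(sites=simulate_occupancy(sites, p), regulated=[],
                                factor_coloc=pd.DataFrame())
        track = simulate_conservation(truth, p)
        planted_vals = np.concatenate([
            track.values(r.chrom, r.start, r.end) for r in sites.itertuples()])
        n = planted_vals.size
        sd = np.sqrt(0.8 * 0.2 / (p.conservation_concentration + 1))
        assert abs(planted_vals.mean() - 0.8) < 3 * sd / np.sqrt(n) + 0.01
        bg = track.values(p.chrom, 0, 5000)
        mask = np.ones(5000, bool)
        for r in sites.itertuples():
            if r.start < 5000:
                mask[r.start:min(5000, r.end)] = False
        assert bg[mask].mean() < 0.2

    def test_zero_concentration_constant(self):
        p = SimulationParams(seed=6, conservation_concentration=0.0, **SMALL)
        truth = SimulationTruth(
            sites=pd.DataFrame(columns=["chrom", "start", "end", "strand", "motif_id"]),
            regulated=[], factor_coloc=pd.DataFrame())
        track = simulate_conservation(truth, p)
        vals = track.values(p.chrom, 0, 1000)
        assert np.allclose(vals, p.conservation_background_mean)


class TestGenesAndRegulation:
    def test_regulated_count_deterministic(self):
        p = SimulationParams(seed=9, regulated_fraction=0.1, **SMALL)
        genome = simulate_genome(p)
        _, sites = plant_sites(genome, synthetic_mre_motif(), p.n_sites, p)
        genes, regulated = simulate_annotation_and_genes(p, sites)
        assert len(genes) == p.n_genes
        assert len(regulated) == round(0.1 * p.n_genes)

    def test_genes_non_overlapping_with_exons_inside(self):
        p = SimulationParams(seed=9, **SMALL)
        genome = simulate_genome(p)
        _, sites = plant_sites(genome, synthetic_mre_motif(), p.n_sites, p)
        genes, _ = simulate_annotation_and_genes(p, sites)
        ordered = sorted(genes, key=lambda g: g.start)
        assert all(a.end <= b.start for a, b in zip(ordered, ordered[1:]))

    def test_direction_split_binomial(self):
        p = SimulationParams(genome_length=2_000_000, n_sites=200, n_genes=400,
                             regulated_fraction=0.5, seed=11)
        genome = simulate_genome(p)
        _, sites = plant_sites(genome, synthetic_mre_motif(), p.n_sites, p)
        _, regulated = simulate_annotation_and_genes(p, sites)
        n = len(regulated)
        pos = sum(r.direction == "positive" for r in regulated)
        assert abs(pos - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_infeasible_packing_rejected(self):
        p = SimulationParams(seed=9, genome_length=50_000, n_genes=100,
                             gene_length_min=1000, gene_length_max=1200)
        with pytest.raises(ValueError):
            simulate_annotation_and_genes(p, pd.DataFrame(columns=["start", "end"]))


class TestPeaks:
    def _setup(self, prob_pos, prob_other, seed=13):
        p = SimulationParams(seed=seed, regulated_fraction=0.3, **SMALL)
        ds = simulate_dataset(SimulationParams(
            seed=seed, regulated_fraction=0.3,
            factors=(FactorSpec("f", prob_pos=prob_pos, prob_neg=prob_other,
                                prob_other=prob_other, background_per_mb=0.0),),
            **SMALL))
        return ds

    def test_full_colocalization_no_background(self):
        ds = self._setup(prob_pos=1.0, prob_other=1.0)
        peaks = ds.factor_peaks["f"]
        assert len(peaks) == len(ds.truth.sites)
        mids = ds.truth.sites[["start", "end"]].sum(axis=1) // 2
        starts = np.array([iv.start for iv in peaks])
        ends = np.array([iv.end for iv in peaks])
        for mid in mids:
            assert ((starts <= mid) & (mid < ends)).any()

    def test_zero_colocalization(self):
        ds = self._setup(prob_pos=0.0, prob_other=0.0)
        assert len(ds.factor_peaks["f"]) == 0


class TestTruthAndDeterminism:
    def test_truth_roundtrip(self, tmp_path):
        p = SimulationParams(seed=1, regulated_fraction=0.2,
                             factors=(FactorSpec("f", prob_pos=0.5),), **SMALL)
        ds = simulate_dataset(p)
        ds.truth.to_dir(str(tmp_path / "truth"))
        back = SimulationTruth.from_dir(str(tmp_path / "truth"))
        pd.testing.assert_frame_equal(back.sites, ds.truth.sites)
        assert back.regulated == ds.truth.regulated
        pd.testing.assert_frame_equal(back.factor_coloc, ds.truth.factor_coloc)

    def test_end_to_end_determinism(self):
        p = SimulationParams(seed=17, **SMALL)
        d1 = simulate_dataset(p)
        d2 = simulate_dataset(p)
        assert d1.genome == d2.genome
        pd.testing.assert_frame_equal(d1.truth.sites, d2.truth.sites)
        assert d1.footprints["cell1"] == d2.footprints["cell1"]
        assert list(d1.conservation.records())[:100] == list(d2.conservation.records())[:100]

    def test_recall_monotone_in_sensitivity(self):
        """Measured recall of the caller never decreases with footprint
        sensitivity."""
        recalls = []
        for sens in (0.3, 0.7, 1.0):
            p = SimulationParams(seed=21, footprint_sensitivity=sens, **SMALL)
            ds = simulate_dataset(p)
            hits = scan_genome(ds.genome, [ds.motif])
            calls, _ = call_footprints(hits, ds.footprints["cell1"],
                                       ds.conservation, AnalysisConfig(),
                                       motifs={ds.motif.motif_id: ds.motif})
            recalls.append(evaluate_calls(calls, ds.truth, "cell1")["recall"])
        assert recalls[0] <= recalls[1] <= recalls[2]
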