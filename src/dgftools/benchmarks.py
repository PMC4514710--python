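"""Self-contained benchmark experiments on synthetic data.

Each function simulates its inputs from a seed, runs the relevant pipeline
stages and measures an operating characteristic: planted-site recovery of
the footprint caller, selection rates of the co-regulator screen, the
cross-cell random-panel control, and the null calibration of the Monte
Carlo enrichment test. Problem sizes follow the generator defaults (1 Mb
genome, 500 planted sites) unless stated.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import AnalysisConfig
from .coreg import footprints_near_regulated_tss, screen_factors
from .footprints import call_footprints, supporting_footprints
from .intervals import GenomicInterval, IntervalSet
from .motifs import scan_genome
from .multicell import random_panel_control
from .simulate import (FactorSpec, SimulationParams, evaluate_calls,
                       rng_for, simulate_dataset)
from .stats import monte_carlo_test


def footprint_recovery(seed: int = 0, cell: str = "cell1",
                       params: Optional[SimulationParams] = None) -> dict:
    """Recall/precision of the footprint caller on the default simulation
    (footprint sensitivity 0.95, conservation means 0.8 planted / 0.1
    background, thresholds 0.9 and 0.22)."""
    params = params or SimulationParams(seed=seed)
    ds = simulate_dataset(params)
    hits = scan_genome(ds.genome, [ds.motif])
    cfg = AnalysisConfig()
    calls, _ = call_footprints(hits, ds.footprints[cell], ds.conservation, cfg,
                               motifs={ds.motif.motif_id: ds.motif}, cell_type=cell)
    return evaluate_calls(calls, ds.truth, cell)


def _single_coreg_screen(seed: int, mc_repetitions: int = 2000) -> Dict[str, str]:
    """One simulated screen: a factor co-localised with footprints at
    positively regulated genes (probability 0.5) versus an unrelated factor
    (background probability 0.05 everywhere). Returns each factor's assigned
    set ("positive"/"negative"/"none")."""
    params = SimulationParams(
        seed=seed,
        cell_types=("cell1",),
        regulated_fraction=0.3,
        factors=(
            FactorSpec("planted", prob_pos=0.5, prob_neg=0.05, prob_other=0.05),
            FactorSpec("unrelated", prob_pos=0.05, prob_neg=0.05, prob_other=0.05),
        ),
    )
    ds = simulate_dataset(params)
    hits = scan_genome(ds.genome, [ds.motif])
    cfg = AnalysisConfig(mc_repetitions=mc_repetitions)
    calls, _ = call_footprints(hits, ds.footprints["cell1"], ds.conservation, cfg,
                               motifs={ds.motif.motif_id: ds.motif}, cell_type="cell1")
    pool = ds.footprints["cell1"]
    case = supporting_footprints(calls, pool)
    pos, neg = footprints_near_regulated_tss(case, ds.regulated, ds.genes,
                                             window=cfg.coreg_window)
    results = screen_factors(ds.factor_peaks, pos, neg, pool, cfg, seed=seed)
    return {r.factor: r.assigned_set for r in results}


def coreg_screen_replicates(n_screens: int = 100, seed: int = 0,
                            mc_repetitions: int = 2000) -> dict:
    """Selection rates over repeated simulated screens."""
    planted_pos = 0
    unrelated_selected = 0
    for i in range(n_screens):
        assigned = _single_coreg_screen(seed * 100_003 + i, mc_repetitions)
        planted_pos += assigned["planted"] == "positive"
        unrelated_selected += assigned["unrelated"] != "none"
    return {
        "n_screens": n_screens,
        "planted_positive_rate": planted_pos / n_screens,
        "unrelated_selected_rate": unrelated_selected / n_screens,
    }


def random_panel_zero_fraction(seed: int = 0, repetitions: int = 10,
                               n_cells: int = 6, pool_size: int = 2000,
                               sample_size: int = 1000,
                               genome_length: int = 1_000_000) -> dict:
    """Cross-cell negative control: independent random footprint panels
    should share (essentially) no common footprints."""
    rng = rng_for(seed, "random-panel")
    panels: List[Tuple[str, IntervalSet]] = []
    for c in range(n_cells):
        starts = rng.integers(0, genome_length - 30, size=pool_size)
        widths = rng.integers(10, 31, size=pool_size)
        panels.append((
            f"cell{c+1}",
            IntervalSet((GenomicInterval("chrSim", int(s), int(s + w))
                         for s, w in zip(starts, widths)), label=f"cell{c+1}"),
        ))
    curves = random_panel_control(panels, [sample_size] * n_cells,
                                  repetitions=repetitions, seed=seed)
    finals = [curve[-1][1] for curve in curves]
    return {
        "repetitions": repetitions,
        "final_counts": finals,
        "zero_fraction": float(np.mean([f == 0 for f in finals])),
    }


def null_calibration(n_tests: int = 200, seed: int = 0,
                     pool_size: int = 4000, case_size: int = 1600,
                     n_query: int = 400, query_width: int = 1000,
                     genome_length: int = 2_000_000,
                     repetitions: int = 10000) -> dict:
    """Type-I error of the Monte Carlo test under a null where the query is
    independent of the case labels.

    Uses the fixed-direction one-sided test, under which the p-value is
    (conservatively, because the overlap count is discrete) uniform; the
    problem sizes are chosen large enough that the attainable significance
    levels lie close to the nominal one.
    """
    rng = rng_for(seed, "null-calibration")
    hits = 0
    for _ in range(n_tests):
        starts = rng.integers(0, genome_length - 30, size=pool_size)
        widths = rng.integers(10, 31, size=pool_size)
        pool = IntervalSet(
            (GenomicInterval("chrN", int(s), int(s + w)) for s, w in zip(starts, widths)))
        chosen = rng.choice(pool_size, size=case_size, replace=False)
        case = IntervalSet((pool[int(i)] for i in chosen))
        q_starts = rng.integers(0, genome_length - query_width, size=n_query)
        query = IntervalSet(
            (GenomicInterval("chrN", int(s), int(s) + query_width) for s in q_starts))
        res = monte_carlo_test(case, pool, query, repetitions=repetitions,
                               rng=rng, alternative="greater")
        hits += res.p_value < 0.05
    return {"n_tests": n_tests, "fraction_significant": hits / n_tests}
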