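"""Midpoint-overlap contingency, normalised ratio, Monte Carlo test, FDR."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as ss

from dgftools.intervals import GenomicInterval, IntervalSet
from dgftools.stats import (OverlapContingency, bh_fdr,
                            hypergeometric_expectation, midpoint_overlap_count,
                            monte_carlo_test, normalized_ratio)

from conftest import make_intervals


class TestMidpointOverlapCount:
    def test_containment_definition(self):
        fp = make_intervals([(100, 110)])          # midpoint 105
        assert midpoint_overlap_count(fp, make_intervals([(105, 106)])) == 1
        assert midpoint_overlap_count(fp, make_intervals([(106, 120)])) == 0

    def test_disjoint_chromosomes(self):
        fp = make_intervals([(100, 110)], chrom="chr1")
        q = make_intervals([(0, 1000)], chrom="chr2")
        assert midpoint_overlap_count(fp, q) == 0

    def test_overlapping_query_counts_once(self):
        fp = make_intervals([(100, 110)])
        q = make_intervals([(100, 200), (104, 106)])
        assert midpoint_overlap_count(fp, q) == 1

    def test_brute_force_oracle(self, rng):
        for _ in range(300):
            fps = [(int(s), int(s) + int(rng.integers(1, 20)))
                   for s in rng.integers(0, 480, int(rng.integers(1, 10)))]
            qs = [(int(s), int(s) + int(rng.integers(1, 40)))
                  for s in rng.integers(0, 480, int(rng.integers(0, 6)))]
            expected = sum(
                1 for s, e in fps
                if any(a <= (s + e) // 2 < b for a, b in qs))
            got = midpoint_overlap_count(make_intervals(fps), make_intervals(qs))
            assert got == expected


class TestNormalizedRatio:
    def test_equal_rates_is_one(self):
        assert normalized_ratio(OverlapContingency(10, 20, 100, 200)) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert normalized_ratio(OverlapContingency(30, 10, 100, 200)) == pytest.approx(6.0)

    def test_zero_cases(self):
        assert normalized_ratio(OverlapContingency(0, 10, 100, 200)) == 0.0
        assert normalized_ratio(OverlapContingency(5, 0, 100, 200)) == float("inf")
        assert math.isnan(normalized_ratio(OverlapContingency(0, 0, 100, 200)))

    def test_contingency_invariants(self):
        with pytest.raises(ValueError):
            OverlapContingency(5, 0, 4, 10)
        with pytest.raises(ValueError):
            OverlapContingency(0, 0, 0, 10)


def _pool_with_marked(n_marked, n_total, spacing=1000, width=10):
    """Pool of footprints; the first n_marked midpoints sit inside the query."""
    fps = [GenomicInterval("chr1", i * spacing, i * spacing + width)
           for i in range(n_total)]
    query = make_intervals([(i * spacing, i * spacing + width) for i in range(n_marked)])
    return IntervalSet(fps), query


class TestMonteCarloTest:
    def test_exact_hypergeometric_oracle(self):
        """Pool of 10 (n=5), K=4 overlapping footprints all in the case set:
        the exact enrichment probability is C(4,4)C(6,1)/C(10,5) = 6/252,
        verified here by exhaustive enumeration of all 252 splits."""
        pool, query = _pool_with_marked(4, 10)
        case = IntervalSet(pool.intervals[:5])   # contains all 4 marked + 1
        # exhaustive enumeration oracle for P(T >= T_obs)
        marked = set(range(4))
        t_obs = 2 * 4 - 4
        extreme = total = 0
        for combo in itertools.combinations(range(10), 5):
            x = len(marked & set(combo))
            total += 1
            extreme += (2 * x - 4) >= t_obs
        exact = extreme / total
        assert exact == pytest.approx(6 / 252)
        res = monte_carlo_test(case, pool, query, repetitions=10_000, seed=7)
        se = math.sqrt(exact * (1 - exact) / 10_000)
        assert res.direction == "positive"
        assert abs(res.p_value - exact) < 3 * se + 1 / 10_001
        assert res.contingency == OverlapContingency(4, 0, 5, 5)

    def test_degenerate_query(self):
        pool, _ = _pool_with_marked(0, 10)
        case = IntervalSet(pool.intervals[:5])
        query = make_intervals([(900_000, 900_100)])
        res = monte_carlo_test(case, pool, query, repetitions=1000, seed=1)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_same_seed_identical(self):
        pool, query = _pool_with_marked(6, 20)
        case = IntervalSet(pool.intervals[:8])
        r1 = monte_carlo_test(case, pool, query, repetitions=2000, seed=42)
        r2 = monte_carlo_test(case, pool, query, repetitions=2000, seed=42)
        assert r1.p_value == r2.p_value

    def test_case_must_be_subset_of_pool(self):
        pool, query = _pool_with_marked(2, 10)
        outsider = IntervalSet([GenomicInterval("chr9", 0, 10)])
        with pytest.raises(ValueError):
            monte_carlo_test(outsider, pool, query, repetitions=1000, seed=0)

    def test_direction_agrees_with_ratio(self):
        pool, query = _pool_with_marked(6, 20)
        enriched = IntervalSet(pool.intervals[:6])      # all marked
        depleted = IntervalSet(pool.intervals[10:16])   # none marked
        r_enr = monte_carlo_test(enriched, pool, query, repetitions=1000, seed=0)
        r_dep = monte_carlo_test(depleted, pool, query, repetitions=1000, seed=0)
        assert r_enr.direction == "positive" and r_enr.ratio > 1
        assert r_dep.direction == "negative" and r_dep.ratio < 1

    def test_two_sided_at_least_one_sided(self):
        pool, query = _pool_with_marked(6, 20)
        case = IntervalSet(pool.intervals[:8])
        one = monte_carlo_test(case, pool, query, repetitions=5000, seed=3,
                               alternative="auto")
        two = monte_carlo_test(case, pool, query, repetitions=5000, seed=3,
                               alternative="two-sided")
        assert two.p_value >= one.p_value


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == [pytest.approx(0.03)]

    def test_hand_step_up(self):
        got = bh_fdr([0.01, 0.04, 0.03, 0.005])
        assert got == pytest.approx([0.02, 0.04, 0.04, 0.02])

    def test_ties_all_equal(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_empty(self):
        assert bh_fdr([]) == []

    def test_pointwise_geq_and_permutation_invariant(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        adj = np.array(bh_fdr(list(p)))
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        perm = rng.permutation(50)
        adj_perm = np.array(bh_fdr(list(p[perm])))
        assert np.allclose(adj_perm, adj[perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestHypergeometricExpectation:
    def test_closed_form(self):
        assert hypergeometric_expectation(1000, 100, 50) == pytest.approx(5.0)
        assert hypergeometric_expectation(100, 0, 50) == 0.0
        with pytest.raises(ValueError):
            hypergeometric_expectation(0, 0, 0)

    def test_sampling_oracle(self, rng):
        N, K, n = 200, 60, 40
        draws = [
            np.intersect1d(rng.choice(N, n, replace=False), np.arange(K)).size
            for _ in range(10_000)
        ]
        assert hypergeometric_expectation(N, K, n) == pytest.approx(
            np.mean(draws), rel=0.02)
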