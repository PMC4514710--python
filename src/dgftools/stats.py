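"""Interval-overlap enrichment statistics.

The central test: given a case set of footprints (e.g. predicted TF
footprints), the pool they came from (all DNase I footprints) and a query
dataset (e.g. ChIP-seq peaks), count midpoints falling inside the query,
form the contingency (X, Y, n, m), summarise effect size with the
normalised ratio r = (X/n)/(Y/m), and obtain an empirical p-value by
resampling case-sized subsets from the pool.

Because X + Y is fixed across resamples, the test statistic T = X - Y
equals 2X - K (K = pool midpoints in the query), and sampling n footprints
without replacement makes X exactly hypergeometric; each Monte Carlo
repetition therefore draws X from Hypergeometric(N, K, n), which is
distributionally identical to resampling indices and far cheaper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet, points_in_set


@dataclass(frozen=True)
class OverlapContingency:
    """X of n case footprints and Y of m control footprints hit the query."""

    X: int
    Y: int
    n: int
    m: int

    def __post_init__(self) -> None:
        if not (0 <= self.X <= self.n and 0 <= self.Y <= self.m):
            raise ValueError("need 0 <= X <= n and 0 <= Y <= m")
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be >= 1")


@dataclass
class EnrichmentResult:
    contingency: OverlapContingency
    ratio: float
    direction: str            # "positive" (enrichment) or "negative" (depletion)
    p_value: float
    p_adjusted: Optional[float]
    repetitions: int
    seed: Optional[int]
    degenerate: bool = False
    label: str = ""


def midpoint_overlap_count(footprints: IntervalSet, query: IntervalSet) -> int:
    """Number of footprints whose midpoint lies inside the query union.

    Query intervals are merged first, so a midpoint covered by several query
    intervals counts once; containment is half-open.
    """
    total = 0
    inside = points_in_set(footprints.midpoints(), query)
    for mask in inside.values():
        total += int(mask.sum())
    return total


def normalized_ratio(c: OverlapContingency) -> float:
    """r = (X/n)/(Y/m). > 1 means the query is enriched among case footprints.

    Y = 0 with X > 0 gives +inf (infinite enrichment); X = Y = 0 gives NaN
    (degenerate: the query misses the pool entirely).
    """
    if c.Y == 0:
        return float("inf") if c.X > 0 else float("nan")
    return (c.X / c.n) / (c.Y / c.m)


def monte_carlo_test(
    case: IntervalSet,
    pool: IntervalSet,
    query: IntervalSet,
    repetitions: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    alternative: str = "auto",
) -> EnrichmentResult:
    """Empirical enrichment test of the case/control midpoint-overlap split.

    ``alternative``: "auto" tests in the direction of the observed deviation
    (the reporting convention for signed findings); "greater"/"less" fix the
    direction; "two-sided" doubles the smaller tail. The p-value uses the
    add-one estimator (1 + #{at least as extreme}) / (repetitions + 1).
    """
    if repetitions < 100:
        raise ValueError("repetitions must be >= 100")
    N, n = len(pool), len(case)
    if n < 1 or n > N:
        raise ValueError("case size must be between 1 and the pool size")
    pool_keys = {}
    for iv in pool:
        pool_keys[(iv.chrom, iv.start, iv.end)] = pool_keys.get((iv.chrom, iv.start, iv.end), 0) + 1
    for iv in case:
        key = (iv.chrom, iv.start, iv.end)
        if pool_keys.get(key, 0) <= 0:
            raise ValueError(f"case interval {key} not found in pool")
        pool_keys[key] -= 1
    m = N - n
    if m < 1:
        raise ValueError("control set is empty (case equals pool)")

    K = midpoint_overlap_count(pool, query)
    X = midpoint_overlap_count(case, query)
    Y = K - X
    contingency = OverlapContingency(X=X, Y=Y, n=n, m=m)
    r = normalized_ratio(contingency)

    if rng is None:
        rng = np.random.default_rng(seed)
    t_obs = X - Y  # = 2X - K
    degenerate = K == 0
    # sample X under the null: n draws without replacement from N with K marked
    x_sim = rng.hypergeometric(K, N - K, n, size=repetitions) if K > 0 else np.zeros(repetitions, dtype=int)
    t_sim = 2 * x_sim - K

    rate_case = X / n
    rate_ctrl = Y / m
    direction = "positive" if rate_case >= rate_ctrl else "negative"

    def tail(side: str) -> float:
        if side == "greater":
            extreme = int((t_sim >= t_obs).sum())
        else:
            extreme = int((t_sim <= t_obs).sum())
        return (1 + extreme) / (repetitions + 1)

    if alternative == "auto":
        p = tail("greater" if direction == "positive" else "less")
    elif alternative in ("greater", "less"):
        p = tail(alternative)
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(tail("greater"), tail("less")))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    return EnrichmentResult(
        contingency=contingency,
        ratio=r,
        direction=direction,
        p_value=p,
        p_adjusted=None,
        repetitions=repetitions,
        seed=seed,
        degenerate=degenerate,
    )


def bh_fdr(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1,
    position-aligned with the input."""
    p = list(pvalues)
    if not p:
        return []
    if any(not (0 < x <= 1) for x in p):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def adjust_results(results: Sequence[EnrichmentResult], groups: Optional[Sequence[str]] = None) -> None:
    """BH-adjust p-values in place, over all results or within groups
    (e.g. per cell type)."""
    if groups is None:
        groups = ["all"] * len(results)
    by_group: Dict[str, List[int]] = {}
    for i, g in enumerate(groups):
        by_group.setdefault(g, []).append(i)
    for idxs in by_group.values():
        adj = bh_fdr([results[i].p_value for i in idxs])
        for i, a in zip(idxs, adj):
            results[i].p_adjusted = a


def hypergeometric_expectation(N: int, K: int, n: int) -> float:
    """Expected overlap count when drawing n of N footprints without
    replacement, K of which hit the query: n*K/N."""
    if N == 0:
        raise ValueError("pool size N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    return n * K / N
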