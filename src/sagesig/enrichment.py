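"""Resampling baseline and binomial enrichment test for gene subsets.

The question: is a gene subset (e.g. a curated literature list) over-
represented in a list of differentially expressed genes, relative to
same-sized random draws from the expressed universe? The baseline hit
ratio is estimated by Monte-Carlo draws without replacement, then the
observed hit count is scored with an exact one-sample binomial test
against that baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats

DEFAULT_ITERATIONS = 100_000


@dataclass
class EnrichmentResult:
    universe_size: int
    subset_size: int
    de_list_size: int
    observed_hits: int
    observed_ratio: float
    simulated_baseline_ratio: float
    analytic_expectation: float
    iterations: int
    seed: int
    alternative: str
    p_binomial: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def simulate_baseline(
    universe: Iterable[str],
    subset_size: int,
    de_list: Iterable[str],
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Mean hit ratio of random same-sized subsets.

    Each iteration draws ``subset_size`` genes uniformly without
    replacement from ``universe`` and records the fraction falling in
    ``de_list``. Returns the mean ratio and the per-iteration ratios.
    Fully determined by ``seed``.
    """
    universe = sorted(set(universe))
    de_set = set(de_list)
    if not de_set <= set(universe):
        raise ValueError("de_list must be a subset of the universe")
    n = len(universe)
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} exceeds universe size {n}")
    if subset_size < 1:
        raise ValueError("subset_size must be >= 1")
    hit = np.array([g in de_set for g in universe], dtype=np.int8)
    rng = np.random.default_rng(seed)
    hits = np.empty(iterations, dtype=np.int64)
    for i in range(iterations):
        idx = rng.choice(n, size=subset_size, replace=False)
        hits[i] = int(hit[idx].sum())
    ratios = hits / float(subset_size)
    return float(ratios.mean()), ratios


def binomial_enrichment(
    observed_hits: int,
    subset_size: int,
    baseline_p: float,
    alternative: str = "greater",
) -> float:
    """Exact binomial tail probability of the observed hit count under
    Binomial(subset_size, baseline_p)."""
    if not 0 <= observed_hits <= subset_size:
        raise ValueError("observed_hits out of range")
    if not 0.0 < baseline_p < 1.0:
        raise ValueError("baseline_p must be strictly between 0 and 1")
    if alternative not in ("greater", "two-sided", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    result = stats.binomtest(
        observed_hits, subset_size, baseline_p, alternative=alternative
    )
    return float(result.pvalue)


def run_enrichment(
    universe: Iterable[str],
    subset: Iterable[str],
    de_list: Iterable[str],
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Full enrichment test of ``subset`` within ``de_list``."""
    universe = sorted(set(universe))
    subset = set(subset)
    de_set = set(de_list)
    if not subset <= set(universe):
        raise ValueError("subset must be contained in the universe")
    observed = len(subset & de_set)
    mean_ratio, _ = simulate_baseline(
        universe, len(subset), de_set, iterations=iterations, seed=seed
    )
    if 0.0 < mean_ratio < 1.0:
        p = binomial_enrichment(observed, len(subset), mean_ratio, alternative)
    else:
        # degenerate baseline: an empty (or exhaustive) DE list cannot be
        # enriched; any hits against an empty baseline are impossible
        # under the null
        p = 1.0 if observed == (0 if mean_ratio == 0.0 else len(subset)) else 0.0
    return EnrichmentResult(
        universe_size=len(universe),
        subset_size=len(subset),
        de_list_size=len(de_set),
        observed_hits=observed,
        observed_ratio=observed / len(subset) if subset else 0.0,
        simulated_baseline_ratio=mean_ratio,
        analytic_expectation=len(de_set) / len(universe),
        iterations=iterations,
        seed=seed,
        alternative=alternative,
        p_binomial=p,
    )
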