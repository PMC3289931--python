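"""Two-proportion z-test differential expression between count libraries.

The test statistic for a gene with counts ``c_a``/``c_b`` in libraries of
sizes ``n_a``/``n_b`` is the pooled two-proportion z-test::

    p_a = c_a/n_a,  p_b = c_b/n_b,  p0 = (c_a+c_b)/(n_a+n_b)
    z = (p_a - p_b) / sqrt(p0*(1-p0)*(1/n_a + 1/n_b))

with a two-sided normal tail probability. ``z**2`` equals the 1-df Pearson
chi-square statistic of the corresponding 2x2 table without continuity
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import stats

from sagesig.libnorm import NormalizedLibrary
from sagesig.sagetags import GeneCounts

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_COUNT = 2

CountsLike = Union[GeneCounts, NormalizedLibrary, Mapping[str, float]]


def _counts_of(lib: CountsLike) -> Mapping[str, float]:
    if isinstance(lib, (GeneCounts, NormalizedLibrary)):
        return lib.counts
    return lib


def _total_of(lib: CountsLike) -> float:
    if isinstance(lib, NormalizedLibrary):
        return lib.total
    counts = _counts_of(lib)
    return float(sum(counts.values()))


@dataclass
class DifferentialResult:
    gene_id: str
    count_a: float
    count_b: float
    n_a: float
    n_b: float
    proportion_a: float
    proportion_b: float
    z: float
    p: float
    direction: str  # up_in_a | down_in_a | equal
    significant: bool
    unique_to: str  # a | b | none


@dataclass
class ConsistentDESet:
    """Genes consistently differential across every required comparison."""

    up_genes: set[str]
    down_genes: set[str]
    unique_up: set[str] = field(default_factory=set)
    per_comparison: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("up and down sets overlap")


def ztest_counts(
    c_a: float, n_a: float, c_b: float, n_b: float
) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided p-value.

    Counts may be real-valued (normalized libraries). A gene absent from
    both libraries is not testable and raises ``ValueError``.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library sizes must be positive")
    if c_a < 0 or c_b < 0 or c_a > n_a or c_b > n_b:
        raise ValueError("counts must satisfy 0 <= c <= n")
    if c_a == 0 and c_b == 0:
        raise ValueError("gene absent from both libraries: not testable")
    p_a = c_a / n_a
    p_b = c_b / n_b
    if p_a == p_b:
        return 0.0, 1.0
    p0 = (c_a + c_b) / (n_a + n_b)
    se = math.sqrt(p0 * (1.0 - p0) * (1.0 / n_a + 1.0 / n_b))
    z = (p_a - p_b) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(p, 1.0)


def _ztest_arrays(
    c_a: np.ndarray, n_a: float, c_b: np.ndarray, n_b: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled z-test; entries with both counts zero get z=0, p=1."""
    p_a = c_a / n_a
    p_b = c_b / n_b
    p0 = (c_a + c_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(p0 * (1.0 - p0) * (1.0 / n_a + 1.0 / n_b))
        z = np.where(p_a == p_b, 0.0, (p_a - p_b) / se)
    z = np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0)
    p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return z, p


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def pairwise_de(
    lib_a: CountsLike,
    lib_b: CountsLike,
    alpha: float = DEFAULT_ALPHA,
    min_count: float = DEFAULT_MIN_COUNT,
    n_a: float | None = None,
    n_b: float | None = None,
    correction: str = "none",
) -> list[DifferentialResult]:
    """Per-gene z-tests over the universe defined by the reference library.

    The tested universe is every gene with count >= ``min_count`` in
    ``lib_a``. Genes expressed in ``lib_a`` but absent from ``lib_b`` are
    flagged ``unique_to='a'``. ``correction`` is ``none`` (default; raw
    p-values against ``alpha``) or ``bh`` (Benjamini-Hochberg).
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    counts_a = _counts_of(lib_a)
    counts_b = _counts_of(lib_b)
    total_a = float(n_a) if n_a is not None else _total_of(lib_a)
    total_b = float(n_b) if n_b is not None else _total_of(lib_b)
    genes = sorted(g for g, c in counts_a.items() if c >= min_count)
    ca = np.array([counts_a[g] for g in genes], dtype=float)
    cb = np.array([counts_b.get(g, 0.0) for g in genes], dtype=float)
    z, p = _ztest_arrays(ca, total_a, cb, total_b)
    p_crit = benjamini_hochberg(p) if (correction == "bh" and len(genes)) else p
    results = []
    for i, gene in enumerate(genes):
        pa = ca[i] / total_a
        pb = cb[i] / total_b
        if pa > pb:
            direction = "up_in_a"
        elif pa < pb:
            direction = "down_in_a"
        else:
            direction = "equal"
        results.append(
            DifferentialResult(
                gene_id=gene,
                count_a=float(ca[i]),
                count_b=float(cb[i]),
                n_a=total_a,
                n_b=total_b,
                proportion_a=pa,
                proportion_b=pb,
                z=float(z[i]),
                p=float(p[i]),
                direction=direction,
                significant=bool(p_crit[i] < alpha),
                unique_to="a" if cb[i] == 0 else "none",
            )
        )
    return results


def consistent_de(
    met_libs: Sequence[CountsLike],
    virtual_nm: NormalizedLibrary,
    alpha: float = DEFAULT_ALPHA,
    min_count: float = DEFAULT_MIN_COUNT,
    consistency: str = "per_library",
    met_ids: Sequence[str] | None = None,
) -> ConsistentDESet:
    """Genes expressed in every metastatic library and consistently
    differential against the virtual reference.

    A gene is *up* when expressed (>= ``min_count``) in all metastatic
    libraries and either significantly higher than the reference in every
    comparison (``per_library``) / in the pooled comparison (``pooled``),
    or absent from the reference altogether (unique, counted as up).
    *Down* is symmetric, requiring significantly lower expression in every
    required comparison.
    """
    if consistency not in ("per_library", "pooled"):
        raise ValueError(f"unknown consistency mode {consistency!r}")
    met_counts = [_counts_of(lib) for lib in met_libs]
    met_totals = [_total_of(lib) for lib in met_libs]
    if met_ids is None:
        met_ids = [
            lib.library_id if hasattr(lib, "library_id") else f"met{i + 1}"
            for i, lib in enumerate(met_libs)
        ]
    nm_total = virtual_nm.total

    core = None
    for counts in met_counts:
        expressed = {g for g, c in counts.items() if c >= min_count}
        core = expressed if core is None else core & expressed
    core = sorted(core or set())

    up: set[str] = set()
    down: set[str] = set()
    unique_up: set[str] = set()
    per_comparison: dict[str, dict[str, tuple[float, float]]] = {
        lid: {} for lid in met_ids
    }

    if core:
        nm = np.array([virtual_nm.get(g) for g in core], dtype=float)
        zs, ps, dirs = [], [], []
        for counts, total, lid in zip(met_counts, met_totals, met_ids):
            cm = np.array([counts[g] for g in core], dtype=float)
            z, p = _ztest_arrays(cm, total, nm, nm_total)
            zs.append(z)
            ps.append(p)
            dirs.append(np.sign(cm / total - nm / nm_total))
            per_comparison[lid] = {
                g: (float(z[i]), float(p[i])) for i, g in enumerate(core)
            }
        zs, ps, dirs = np.array(zs), np.array(ps), np.array(dirs)

        if consistency == "pooled":
            pooled_c = np.array(
                [sum(counts[g] for counts in met_counts) for g in core],
                dtype=float,
            )
            pooled_n = float(sum(met_totals))
            z_pool, p_pool = _ztest_arrays(pooled_c, pooled_n, nm, nm_total)
            sig_up = (p_pool < alpha) & (pooled_c / pooled_n > nm / nm_total)
            sig_down = (p_pool < alpha) & (pooled_c / pooled_n < nm / nm_total)
        else:
            sig_up = np.all((ps < alpha) & (dirs > 0), axis=0)
            sig_down = np.all((ps < alpha) & (dirs < 0), axis=0)

        for i, gene in enumerate(core):
            if nm[i] == 0:
                up.add(gene)
                unique_up.add(gene)
            elif sig_up[i]:
                up.add(gene)
            elif sig_down[i]:
                down.add(gene)

    return ConsistentDESet(
        up_genes=up,
        down_genes=down,
        unique_up=unique_up,
        per_comparison=per_comparison,
    )


@dataclass
class ClusterSizeBias:
    mean_de: float | None
    mean_non_de: float | None
    n_de: int
    n_non_de: int


def cluster_size_bias(
    counts: Mapping[str, float],
    de_genes: set[str],
    universe: set[str] | None = None,
    subset: set[str] | None = None,
) -> ClusterSizeBias:
    """Mean per-gene count ("cluster size") of differential vs
    non-differential genes, optionally restricted to a gene subset."""
    genes = set(counts) if universe is None else set(universe)
    if subset is not None:
        genes &= subset
    de_vals = [counts.get(g, 0.0) for g in genes if g in de_genes]
    non_vals = [counts.get(g, 0.0) for g in genes if g not in de_genes]
    return ClusterSizeBias(
        mean_de=float(np.mean(de_vals)) if de_vals else None,
        mean_non_de=float(np.mean(non_vals)) if non_vals else None,
        n_de=len(de_vals),
        n_non_de=len(non_vals),
    )


def write_de_table(results: Sequence[DifferentialResult], path) -> None:
    """TSV results table, one row per tested gene."""
    with open(path, "w") as handle:
        handle.write(
            "gene_id\tcount_a\tcount_b\tn_a\tn_b\tz\tp\tdirection\t"
            "significant\tunique_to\n"
        )
        for r in sorted(results, key=lambda r: (r.p, r.gene_id)):
            handle.write(
                f"{r.gene_id}\t{r.count_a:g}\t{r.count_b:g}\t{r.n_a:g}\t"
                f"{r.n_b:g}\t{r.z:.6g}\t{r.p:.6g}\t{r.direction}\t"
                f"{int(r.significant)}\t{r.unique_to}\n"
            )
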