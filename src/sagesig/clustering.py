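"""Hierarchical correlation clustering of expression libraries.

Libraries are compared by centered Pearson correlation over a filtered
gene universe (count >= 2 in at least one library by default), turned
into distances d = 1 - r, and clustered agglomeratively. The dendrogram
carries cophenetic distances for farthest-pair queries and serializes to
Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class GeneExpressionTable:
    """Library x gene matrix of non-negative expression values."""

    libraries: list[str]
    genes: list[str]
    values: np.ndarray
    scale: str = "normalized"  # raw | normalized

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.libraries), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.libraries)} libraries x {len(self.genes)} genes"
            )
        if (self.values < 0).any():
            raise ValueError("negative expression values")
        if self.scale not in ("raw", "normalized"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @classmethod
    def from_libraries(cls, libs, scale: str = "normalized") -> "GeneExpressionTable":
        """Build from objects with ``library_id`` and ``counts`` mappings."""
        genes = sorted({g for lib in libs for g in lib.counts})
        values = np.array(
            [[lib.counts.get(g, 0.0) for g in genes] for lib in libs]
        )
        return cls(
            libraries=[lib.library_id for lib in libs],
            genes=genes,
            values=values,
            scale=scale,
        )


@dataclass
class Dendrogram:
    """Agglomerative clustering result over library leaves."""

    leaves: list[str]
    merges: np.ndarray  # scipy linkage matrix
    cophenetic: np.ndarray  # square matrix, leaf order = leaves
    linkage_method: str = "average"

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    def to_newick(self) -> str:
        """Newick string; branch lengths from half merge heights so that
        leaf-to-leaf path length equals the cophenetic distance."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}

        def render(node: int) -> str:
            if node < n:
                return self.leaves[node]
            left, right, h, _ = self.merges[node - n]
            parts = []
            for child in (int(left), int(right)):
                length = h / 2.0 - height[child] / 2.0
                parts.append(f"{render(child)}:{length:.6g}")
            height[node] = h
            return "(" + ",".join(parts) + ")"

        root = n + len(self.merges) - 1
        # render children bottom-up so heights are known
        for node in range(n, root + 1):
            left, right, h, _ = self.merges[node - n]
            height[node] = h
        return render(root) + ";"


def correlation_distance(
    table: GeneExpressionTable, min_count: float = 2, filter_mode: str = "any"
) -> np.ndarray:
    """Pairwise 1 - Pearson distance over the filtered gene universe.

    Genes are kept when their count is >= ``min_count`` in at least one
    library (``any``, default) or in all libraries (``all``).
    """
    if table.values.shape[0] < 2:
        raise ValueError("need at least two libraries")
    if filter_mode == "any":
        keep = (table.values >= min_count).any(axis=0)
    elif filter_mode == "all":
        keep = (table.values >= min_count).all(axis=0)
    else:
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    filtered = table.values[:, keep]
    if filtered.shape[1] < 2:
        raise ValueError("fewer than two genes pass the filter")
    sd = filtered.std(axis=1)
    if np.any(sd == 0):
        bad = table.libraries[int(np.argmax(sd == 0))]
        raise ValueError(f"constant expression vector in library {bad!r}")
    corr = np.corrcoef(filtered)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip((dist + dist.T) / 2.0, 0.0, 2.0)


def hierarchical_cluster(
    distances: np.ndarray,
    leaves: Sequence[str],
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of a distance matrix."""
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    distances = np.asarray(distances, dtype=float)
    if distances.shape != (len(leaves), len(leaves)):
        raise ValueError("distance matrix does not match leaf count")
    condensed = squareform(distances, checks=True)
    merges = hierarchy.linkage(condensed, method=linkage)
    coph = squareform(hierarchy.cophenet(merges))
    return Dendrogram(
        leaves=list(leaves),
        merges=merges,
        cophenetic=coph,
        linkage_method=linkage,
    )


def farthest_pair(dendro: Dendrogram) -> tuple[str, str]:
    """Leaf pair with maximal cophenetic distance; ties broken by the
    lexicographically smallest (sorted) pair."""
    n = len(dendro.leaves)
    if n < 2:
        raise ValueError("need at least two leaves")
    best = None
    best_dist = -np.inf
    for i in range(n):
        for j in range(i + 1, n):
            d = dendro.cophenetic[i, j]
            pair = tuple(sorted((dendro.leaves[i], dendro.leaves[j])))
            if d > best_dist + 1e-12:
                best, best_dist = pair, d
            elif abs(d - best_dist) <= 1e-12 and pair < best:
                best = pair
    return best


def write_distance_matrix(
    distances: np.ndarray, leaves: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("library\t" + "\t".join(leaves) + "\n")
        for name, row in zip(leaves, distances):
            handle.write(name + "\t" + "\t".join(f"{d:.6g}" for d in row) + "\n")
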