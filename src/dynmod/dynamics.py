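"""Per-subject dwell-time profiles and cohort-level meta-modular consensus.

Module labels from independent windowed graphs are arbitrary — label 1 in
one window need not mean label 1 in the next — so consensus across windows
is built on the co-assignment matrix: the fraction of pooled graphs in which
two nodes land in the same module.  Nodes that travel together across the
non-stationary modular configurations have co-assignment near 1 regardless
of labelling; Ward agglomerative clustering of the co-assignment
dissimilarity ``1 - frequency`` then yields the "meta-modular" grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .signed_modularity import Partition, canonicalize_labels

__all__ = [
    "DwellTimeProfile",
    "CoassignmentMatrix",
    "MetaModuleAssignment",
    "module_count_series",
    "modular_dwell_time",
    "coassignment",
    "meta_modules",
]


@dataclass
class DwellTimeProfile:
    """Percentages of a subject's windows spent in each configuration.

    Keys are module counts (for modular dwell time) or sub-network names (for
    strong sub-network dwell time).  When the keys partition all windows —
    as module counts do — the percentages sum to 100.
    """

    subject_id: str
    percentages: dict


@dataclass
class CoassignmentMatrix:
    """Fraction of pooled graphs in which each node pair shares a module label."""

    frequencies: np.ndarray
    n_graphs_pooled: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 2 or f.shape[0] != f.shape[1]:
            raise ValueError("frequencies must be square")
        if not np.allclose(f, f.T, atol=1e-12):
            raise ValueError("frequencies must be symmetric")
        if f.min() < -1e-12 or f.max() > 1 + 1e-12:
            raise ValueError("frequencies must lie in [0, 1]")
        if not np.allclose(np.diag(f), 1.0):
            raise ValueError("diagonal must be 1 (a node always shares its own label)")
        self.frequencies = f


@dataclass
class MetaModuleAssignment:
    """Consensus clusters of nodes plus the Ward merge history that produced them."""

    labels: np.ndarray
    k: int
    linkage_record: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if np.unique(self.labels).size != self.k:
            raise ValueError("labels must contain exactly k distinct values")


def module_count_series(partitions: Sequence[Partition]) -> np.ndarray:
    """Number of modules in each windowed graph, window order preserved."""
    if not partitions:
        raise ValueError("partitions must be non-empty")
    return np.asarray([p.n_modules for p in partitions], dtype=int)


def modular_dwell_time(series: np.ndarray, subject_id: str = "") -> DwellTimeProfile:
    """Percentage of windows spent in each module-count configuration."""
    series = np.asarray(series, dtype=int)
    if series.size == 0:
        raise ValueError("series must be non-empty")
    uniq, counts = np.unique(series, return_counts=True)
    pct = {int(m): 100.0 * c / series.size for m, c in zip(uniq, counts)}
    return DwellTimeProfile(subject_id=subject_id, percentages=pct)


def coassignment(partitions: Sequence[Partition]) -> CoassignmentMatrix:
    """Co-assignment frequencies over all pooled windows (all subjects).

    Invariant to how each window's modules happen to be numbered.
    """
    if not partitions:
        raise ValueError("partitions must be non-empty")
    n = partitions[0].labels.size
    acc = np.zeros((n, n))
    for p in partitions:
        if p.labels.size != n:
            raise ValueError("all partitions must share the same node count")
        acc += p.labels[:, None] == p.labels[None, :]
    freq = acc / len(partitions)
    np.fill_diagonal(freq, 1.0)
    return CoassignmentMatrix(frequencies=freq, n_graphs_pooled=len(partitions))


def meta_modules(coassign: CoassignmentMatrix, k: int = 5) -> MetaModuleAssignment:
    """Ward clustering of co-assignment dissimilarity, cut to ``k`` clusters.

    The dissimilarity is ``1 - frequency``.  The dendrogram is cut by
    replaying the first ``N - k`` merges of the linkage record, which yields
    exactly ``k`` clusters even when merges happen at tied (or zero) heights.
    Deterministic given its input.
    """
    n = coassign.frequencies.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    d = 1.0 - coassign.frequencies
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    z = linkage(squareform(d, checks=False), method="ward")
    # replay merges: scipy labels original nodes 0..n-1, new clusters n, n+1, ...
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in range(n - k):
        a, b = int(z[m, 0]), int(z[m, 1])
        parent[find(a)] = n + m
        parent[find(b)] = n + m
    roots = np.asarray([find(i) for i in range(n)])
    labels = canonicalize_labels(roots)
    return MetaModuleAssignment(labels=labels, k=k, linkage_record=z)
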