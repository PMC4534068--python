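"""Subsimplex detection: geodesic-style distances plus k-medoids.

Points lying on distinct low-dimensional subsimplices of one complex are
contiguous in space, so ordinary Euclidean clustering separates them poorly.
Following the manifold-learning idea, every pair of samples is connected by
an edge weighted with the *squared* Euclidean distance and the metric used
for clustering is the shortest-path length through that complete graph.
Squaring makes long straight hops more expensive than chains of short hops
through the cloud, so the shortest path approximates the geodesic distance
along the point cloud itself: within one subsimplex geodesic and straight
line distances agree, across subsimplices the geodesic is longer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import csgraph_from_dense, shortest_path
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "GeodesicDistances",
    "ClusterAssignment",
    "geodesic_distances",
    "kmedoids_cluster",
    "cluster_count_scan",
]


@dataclass
class GeodesicDistances:
    """All-pairs shortest-path distances (squared-distance edge weights)."""

    dist: np.ndarray

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        n = self.dist.shape[0]
        if self.dist.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.dist, self.dist.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.dist), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n_samples(self) -> int:
        return self.dist.shape[0]


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    medoid_indices: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.medoid_indices = np.asarray(self.medoid_indices, dtype=int)
        if len(self.medoid_indices) != self.k:
            raise ValueError("need exactly k medoids")
        if len(np.unique(self.medoid_indices)) != self.k:
            raise ValueError("medoids must be distinct")
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every cluster must be non-empty")
        for c, m in enumerate(self.medoid_indices):
            if self.labels[m] != c:
                raise ValueError(f"medoid {m} is not labelled with its cluster {c}")


def geodesic_distances(coords: np.ndarray) -> GeodesicDistances:
    """Exact all-pairs shortest paths on the complete squared-Euclidean graph."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite values")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    sq = squareform(pdist(coords, metric="sqeuclidean"))
    # csgraph_from_dense keeps explicit zero-weight edges (coincident
    # samples); a raw dense matrix would treat them as missing edges.
    graph = csgraph_from_dense(sq, null_value=np.inf)
    # Floyd-Warshall: exact, cubic, fine for the sample counts used here
    dist = shortest_path(graph, method="FW", directed=False)
    return GeodesicDistances(dist=dist)


def _total_cost(D: np.ndarray, labels: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[np.arange(len(labels)), medoids[labels]].sum())


def _assign(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # medoids sorted ascending, so argmin ties resolve to the lowest medoid index
    return np.argmin(D[:, medoids], axis=1)


def kmedoids_cluster(
    D: GeodesicDistances,
    coords: np.ndarray,
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterAssignment:
    """k-medoids under the geodesic metric.

    Assignment uses the geodesic distance to the medoids; the medoid update
    takes the cluster member nearest (Euclidean) to the Euclidean mean of
    its cluster, which keeps centers inside the subspace spanned by their
    cluster's data.  Iteration stops when labels and medoids stabilise.
    Best of ``n_restarts`` seeded random initialisations by total
    within-cluster geodesic cost wins.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = D.n_samples
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    if coords.shape[0] != n:
        raise ValueError("coords and distance matrix disagree on sample count")
    rng = np.random.default_rng(seed)
    dist = D.dist
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        labels = _assign(dist, medoids)
        labels, medoids = _repair_empty(dist, labels, medoids)
        for _ in range(max_iter):
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                centre = coords[members].mean(axis=0)
                d2 = ((coords[members] - centre) ** 2).sum(axis=1)
                new_medoids[c] = members[int(np.argmin(d2))]
            order = np.argsort(new_medoids)
            new_medoids = new_medoids[order]
            new_labels = _assign(dist, new_medoids)
            new_labels, new_medoids = _repair_empty(dist, new_labels, new_medoids)
            if np.array_equal(new_labels, labels) and np.array_equal(
                new_medoids, medoids
            ):
                break
            labels, medoids = new_labels, new_medoids
        cost = _total_cost(dist, labels, medoids)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, labels, medoids)
    assert best is not None
    _, labels, medoids = best
    return ClusterAssignment(labels=labels, medoid_indices=medoids, k=k)


def _repair_empty(
    dist: np.ndarray, labels: np.ndarray, medoids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Re-seed any emptied cluster with the point geodesically farthest
    from all current medoids, then re-assign."""
    k = len(medoids)
    for c in range(k):
        if (labels == c).any():
            continue
        min_to_medoid = dist[:, medoids].min(axis=1)
        min_to_medoid[medoids] = -np.inf
        replacement = int(np.argmax(min_to_medoid))
        medoids = medoids.copy()
        medoids[c] = replacement
        order = np.argsort(medoids)
        medoids = medoids[order]
        labels = _assign(dist, medoids)
    return labels, medoids


def cluster_count_scan(
    D: GeodesicDistances,
    coords: np.ndarray,
    k_range,
    n_reps: int = 10,
    seed: int = 0,
    n_restarts: int = 20,
) -> pd.DataFrame:
    """Mean variance of cluster sizes across seeded replicates, per k.

    A low size variance indicates a stable, balanced partition; the operator
    uses this table to pick the number of subsimplices empirically.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for k in sorted(k_range):
        variances = []
        for _ in range(n_reps):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            assign = kmedoids_cluster(
                D, coords, k, n_restarts=n_restarts, seed=rep_seed
            )
            sizes = np.bincount(assign.labels, minlength=k)
            variances.append(float(np.var(sizes)))
        rows.append({"k": k, "mean_size_variance": float(np.mean(variances))})
    return pd.DataFrame(rows)
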