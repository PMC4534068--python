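"""Bootstrap vertex uncertainty, cross-cluster vertex merging, MST phylogeny.

Each cluster's simplex fit is repeated on bootstrap resamples to obtain a
mean position and a positional standard deviation per vertex.  Vertices from
different (or the same) subsimplex whose separation is within the sum of
their standard deviations are deemed the same underlying cell population and
merged, gluing the subsimplices into a single simplicial complex.  A minimum
spanning tree over the merged vertices gives the inferred evolutionary tree
among cell populations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .simplexfit import ObjectiveConfig, SimplexModel, fit_simplex

__all__ = [
    "BootstrapEnsemble",
    "SimplicialComplex",
    "PhylogenyTree",
    "bootstrap_fit",
    "match_vertex_sets",
    "should_merge",
    "build_complex",
    "phylogeny_mst",
]


@dataclass
class BootstrapEnsemble:
    """Vertex matrices from B bootstrap refits, aligned to the first replicate."""

    replicate_K: list[np.ndarray]
    vertex_mean: np.ndarray
    vertex_sd: np.ndarray
    B: int
    fit: SimplexModel | None = None

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if len(self.replicate_K) != self.B:
            raise ValueError("replicate count does not match B")
        m = self.replicate_K[0].shape[0]
        if any(Kb.shape[0] != m for Kb in self.replicate_K):
            raise ValueError("replicates disagree on vertex count after matching")
        self.vertex_mean = np.asarray(self.vertex_mean, dtype=float)
        self.vertex_sd = np.asarray(self.vertex_sd, dtype=float)
        if (self.vertex_sd < 0).any():
            raise ValueError("vertex sd must be nonnegative")

    @property
    def n_vertices(self) -> int:
        return self.vertex_mean.shape[0]


@dataclass
class SimplicialComplex:
    """Merged vertex set plus the per-cluster subsimplex index sets."""

    vertices: np.ndarray  # merged x dims, reduced space
    vertex_sd: np.ndarray
    subsimplices: list[list[int]]
    merge_map: dict[tuple[int, int], int]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.vertex_sd = np.asarray(self.vertex_sd, dtype=float)
        n = self.vertices.shape[0]
        for sub in self.subsimplices:
            if any(not (0 <= i < n) for i in sub):
                raise ValueError("subsimplex references an invalid merged index")
        targets = set(self.merge_map.values())
        if targets and (min(targets) < 0 or max(targets) >= n):
            raise ValueError("merge map references an invalid merged index")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "vertices": self.vertices.tolist(),
                "vertex_sd": self.vertex_sd.tolist(),
                "subsimplices": [list(map(int, s)) for s in self.subsimplices],
                "merge_map": {
                    f"{c}:{v}": int(t) for (c, v), t in sorted(self.merge_map.items())
                },
            },
            indent=1,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


@dataclass
class PhylogenyTree:
    """MST over merged vertices: the inferred tree among cell populations."""

    nodes: list[int]
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.nodes) >= 2 and len(self.edges) != len(self.nodes) - 1:
            raise ValueError("a tree on n nodes needs n-1 edges")

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {v: [] for v in self.nodes}
        for a, b, w in self.edges:
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj

    def to_newick(self) -> str:
        """Newick string rooted at the highest-degree vertex (ties: lowest id),
        with MST edge lengths as branch lengths."""
        if not self.nodes:
            raise ValueError("empty tree")
        if len(self.nodes) == 1:
            return f"v{self.nodes[0]};"
        adj = self.adjacency()
        root = min(self.nodes, key=lambda v: (-len(adj[v]), v))

        def rec(node: int, parent: int | None) -> str:
            children = [(c, w) for c, w in sorted(adj[node]) if c != parent]
            if not children:
                return f"v{node}"
            inner = ",".join(f"{rec(c, node)}:{w:.10g}" for c, w in children)
            return f"({inner})v{node}"

        return rec(root, None) + ";"

    def to_edge_table(self) -> list[dict]:
        return [
            {"source": f"v{a}", "target": f"v{b}", "length": w}
            for a, b, w in self.edges
        ]


def bootstrap_fit(
    X_cluster: np.ndarray,
    m: int,
    cfg: ObjectiveConfig | None = None,
    B: int = 10,
    seed: int = 0,
) -> BootstrapEnsemble:
    """Fit B bootstrap resamples of one cluster and align their vertices.

    Each replicate resamples the cluster's points with replacement (same
    size), refits the simplex, and is matched to the first replicate by
    minimum-cost assignment.  The per-vertex positional sd is the rms
    deviation of the vertex position across aligned replicates (the square
    root of the summed per-dimension variances): the standard deviation of
    the vertex's position in *distance* terms, on the same scale as the
    Euclidean separations it is later compared against when merging.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    cfg = cfg or ObjectiveConfig()
    X = np.atleast_2d(np.asarray(X_cluster, dtype=float))
    n = X.shape[0]
    if n < m:
        raise ValueError(f"cluster of size {n} cannot support m={m} vertices")
    rng = np.random.default_rng(seed)
    replicate_K: list[np.ndarray] = []
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        # resampling can collapse the affine span; retry a few times
        for attempt in range(5):
            try:
                model = fit_simplex(X[idx], m, cfg)
                break
            except ValueError as err:
                if attempt == 4:
                    warnings.warn(f"bootstrap replicate {b} dropped: {err}")
                    model = None
                    break
                idx = rng.integers(0, n, size=n)
        if model is None:
            continue
        Kb = model.K
        if replicate_K:
            perm = match_vertex_sets(replicate_K[0], Kb)
            Kb = Kb[perm]
        replicate_K.append(Kb)
    if len(replicate_K) < 2:
        raise ValueError("fewer than 2 usable bootstrap replicates")
    stack = np.stack(replicate_K)  # B_eff x m x d
    vertex_mean = stack.mean(axis=0)
    per_dim_var = stack.var(axis=0, ddof=1)
    vertex_sd = np.sqrt(per_dim_var.sum(axis=1))
    # a reference fit on the full (un-resampled) cluster, reused by callers
    full_fit = fit_simplex(X, m, cfg)
    return BootstrapEnsemble(
        replicate_K=replicate_K,
        vertex_mean=vertex_mean,
        vertex_sd=vertex_sd,
        B=len(replicate_K),
        fit=full_fit,
    )


def match_vertex_sets(ref_K: np.ndarray, other_K: np.ndarray) -> np.ndarray:
    """Minimum total Euclidean cost matching of two equal-size vertex sets.

    Returns the permutation ``perm`` such that ``other_K[perm]`` aligns with
    ``ref_K`` row by row.
    """
    ref_K = np.atleast_2d(np.asarray(ref_K, dtype=float))
    other_K = np.atleast_2d(np.asarray(other_K, dtype=float))
    if ref_K.shape[0] != other_K.shape[0]:
        raise ValueError(
            f"vertex sets of unequal size: {ref_K.shape[0]} vs {other_K.shape[0]}"
        )
    cost = cdist(ref_K, other_K)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(ref_K.shape[0], dtype=int)
    perm[rows] = cols
    return perm


def should_merge(
    v1: np.ndarray, sd1: float, v2: np.ndarray, sd2: float
) -> bool:
    """Two vertices are indistinct when their Euclidean separation is at most
    the sum of their bootstrap positional standard deviations."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
        raise ValueError("vertex positions must be finite")
    return float(np.linalg.norm(v1 - v2)) <= sd1 + sd2


def build_complex(ensembles: list[BootstrapEnsemble]) -> SimplicialComplex:
    """Merge indistinct vertices (within and across clusters) into a complex.

    The indistinctness relation is evaluated over all vertex pairs and its
    connected components are merged: merged position = mean of members,
    merged sd = max of members.
    """
    if not ensembles:
        raise ValueError("need at least one cluster ensemble")
    originals: list[tuple[int, int]] = []
    positions: list[np.ndarray] = []
    sds: list[float] = []
    for c, ens in enumerate(ensembles):
        for v in range(ens.n_vertices):
            originals.append((c, v))
            positions.append(ens.vertex_mean[v])
            sds.append(float(ens.vertex_sd[v]))
    N = len(originals)
    parent = list(range(N))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i in range(N):
        for j in range(i + 1, N):
            if should_merge(positions[i], sds[i], positions[j], sds[j]):
                union(i, j)

    comp_of: dict[int, int] = {}
    members: list[list[int]] = []
    for i in range(N):
        r = find(i)
        if r not in comp_of:
            comp_of[r] = len(members)
            members.append([])
        members[comp_of[r]].append(i)

    merged_pos = np.array([np.mean([positions[i] for i in mem], axis=0) for mem in members])
    merged_sd = np.array([max(sds[i] for i in mem) for mem in members])
    merge_map = {originals[i]: comp_of[find(i)] for i in range(N)}
    subsimplices: list[list[int]] = []
    for c, ens in enumerate(ensembles):
        sub = sorted({merge_map[(c, v)] for v in range(ens.n_vertices)})
        if len(sub) < 2:
            warnings.warn(
                f"cluster {c}: merging collapsed the subsimplex to a single "
                "shared vertex; retaining it as such"
            )
        subsimplices.append(sub)
    return SimplicialComplex(
        vertices=merged_pos,
        vertex_sd=merged_sd,
        subsimplices=subsimplices,
        merge_map=merge_map,
    )


def phylogeny_mst(cx: SimplicialComplex) -> PhylogenyTree:
    """Minimum spanning tree over the merged vertices (Euclidean weights).

    Kruskal's algorithm with edges sorted by (length, id pair) makes the
    tie-break lexicographic and the result deterministic.
    """
    n = cx.n_vertices
    nodes = list(range(n))
    if n == 1:
        return PhylogenyTree(nodes=nodes, edges=[])
    D = cdist(cx.vertices, cx.vertices)
    cand = sorted(
        (float(D[i, j]), i, j) for i in range(n) for j in range(i + 1, n)
    )
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int, float]] = []
    for w, i, j in cand:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
            edges.append((i, j, w))
            if len(edges) == n - 1:
                break
    return PhylogenyTree(nodes=nodes, edges=edges)
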