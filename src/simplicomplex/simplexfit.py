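"""Noise-tolerant simplex fitting with an MST-regularised objective.

A cluster of samples is modelled as (noisy) convex combinations of the
vertices of a bounding simplex; the vertices are the inferred pure
cell-population profiles and the barycentric weights the mixture fractions.
Rather than requiring the simplex to enclose every point, the fit minimises

    sum_j ||x_j - K f_j||_p  +  gamma * log(mst(K))

where ``mst(K)`` is the length of the minimum spanning tree over the vertex
matrix ``K``.  The first term penalises points outside (or away from) the
simplex; the second scores a candidate simplex by the parsimony of a tree
connecting its vertices, so that sub-fits of different dimension carry
penalties in the same (log-length) units and can be summed into a single
complex-level score.  The classical minimum-volume penalty ``log(vol(K))``
is retained as an alternative.

Optimisation alternates between the mixture fractions F (an exact
simplex-constrained least-squares solve per point) and the vertices K
(bounded quasi-Newton descent with analytic gradients), starting from a
minimum-volume enclosing simplex style initialisation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ObjectiveConfig",
    "SimplexModel",
    "DegenerateSimplexError",
    "estimate_num_vertices",
    "mves_init",
    "solve_fractions",
    "mst_length",
    "simplex_volume",
    "evaluate_objective",
    "fit_simplex",
]

#: floor applied inside log(mst) during line searches so a transiently
#: collapsed candidate does not produce -inf
MST_FLOOR = 1e-9


class DegenerateSimplexError(ValueError):
    """Raised when a penalty would be log(0); fitting floors it instead."""


@dataclass
class ObjectiveConfig:
    """Hyperparameters of the simplex objective and its optimiser.

    gamma : weight of the tree-parsimony (or volume) prior; default 10,
        appropriate for data with noise in the low tens of percent.
    p : order of the per-point residual norm; 1 reflects heavy-tailed
        (log-Laplacian) measurement noise, 2 the Gaussian alternative.
    penalty : 'mst' for log of the vertex minimum-spanning-tree length,
        'volume' for the classical log-volume prior.
    """

    gamma: float = 10.0
    p: int = 1
    penalty: str = "mst"
    max_iter: int = 200
    tol: float = 1e-6
    rel_tol: float = 1e-4
    seed: int = 0
    kstep_maxiter: int = 40
    bound_inflation: float = 0.2

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.p not in (1, 2):
            raise ValueError("p must be 1 or 2")
        if self.penalty not in ("mst", "volume"):
            raise ValueError("penalty must be 'mst' or 'volume'")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.rel_tol < 0:
            raise ValueError("rel_tol must be nonnegative")
        if self.max_iter < 0:
            raise ValueError("max_iter must be nonnegative")


@dataclass
class SimplexModel:
    """A fitted bounding simplex: vertices K, fractions F and objective terms."""

    K: np.ndarray
    F: np.ndarray
    residual_term: float
    penalty_term: float
    objective: float
    gamma: float
    converged: bool
    n_iter: int
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.K.shape[0] < 2:
            raise ValueError("a simplex needs at least 2 vertices")
        if self.F.shape[0] != self.K.shape[0]:
            raise ValueError("F rows must match vertex count")
        if (self.F < -1e-9).any():
            raise ValueError("mixture fractions must be nonnegative")
        colsums = self.F.sum(axis=0)
        if np.abs(colsums - 1.0).max() > 1e-6:
            raise ValueError("mixture fraction columns must sum to 1")
        expected = self.residual_term + self.gamma * self.penalty_term
        if abs(self.objective - expected) > 1e-8 * max(1.0, abs(expected)):
            raise ValueError("objective does not equal residual + gamma*penalty")

    @property
    def n_vertices(self) -> int:
        return self.K.shape[0]


def estimate_num_vertices(
    cluster_points: np.ndarray, threshold: float = 0.05
) -> int:
    """Eigenvalue-spectrum heuristic for the number of simplex vertices.

    One more than the number of principal directions whose variance share
    exceeds ``threshold`` (a simplex spanning a q-dimensional point set has
    q+1 vertices), capped at min(dim+1, n_points).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    X = np.atleast_2d(np.asarray(cluster_points, dtype=float))
    n, d = X.shape
    if n < 3:
        raise ValueError("need at least 3 points to estimate vertex count")
    Xc = X - X.mean(axis=0)
    eig = np.linalg.svd(Xc, compute_uv=False) ** 2
    total = eig.sum()
    if total <= 0:
        warnings.warn("degenerate cluster (all points identical); m=1")
        return 1
    m = 1 + int((eig / total > threshold).sum())
    return min(m, d + 1, n)


def mves_init(points: np.ndarray, m: int, seed: int = 0) -> np.ndarray:
    """Minimum-volume-enclosing-simplex style initial vertex guess.

    Seeds vertices by successive farthest-point selection in the cluster's
    own affine span, then alternates facet offset corrections: each facet is
    translated along its outward normal until it touches the extreme point
    on its side — outward where points stick out (inflation), inward where
    there is slack (deflation toward minimal volume).  Deterministic given
    the input; ``seed`` is accepted for interface symmetry with the
    stochastic stages.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = X.shape
    if m < 2:
        raise ValueError("a simplex needs at least 2 vertices")
    if n < m:
        raise ValueError(f"need at least m={m} points, got {n}")
    centre = X.mean(axis=0)
    Xc = X - centre
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(n, d) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int((S > tol).sum())
    if rank < m - 1:
        raise ValueError(
            f"points span an affine subspace of dimension {rank} < m-1={m - 1}; "
            "reduce the within-cluster dimension (or m) before initialising"
        )
    axes = Vt[: m - 1]  # local span, (m-1) x d
    Y = Xc @ axes.T  # n x (m-1)
    # successive farthest-point selection
    chosen = [int(np.argmax((Y**2).sum(axis=1)))]
    Q = np.zeros((0, m - 1))
    for _ in range(m - 1):
        rel = Y - Y[chosen[0]]
        resid = rel - (rel @ Q.T) @ Q
        dist2 = (resid**2).sum(axis=1)
        dist2[chosen] = -np.inf
        nxt = int(np.argmax(dist2))
        chosen.append(nxt)
        direction = resid[nxt]
        nrm = np.linalg.norm(direction)
        if nrm > 0:
            Q = np.vstack([Q, direction / nrm])
    V = Y[chosen].copy()  # m x (m-1), local-coordinate vertices
    V = _facet_refine(V, Y, rounds=4)
    return centre + V @ axes


def _facet_refine(V: np.ndarray, Y: np.ndarray, rounds: int = 4) -> np.ndarray:
    """Alternating facet offset corrections toward a tight enclosing simplex.

    For each vertex's opposite facet, shift the facet (all other vertices)
    along its outward normal so it passes through the extreme point on its
    side.  Positive shifts enclose stragglers, negative shifts remove slack.
    """
    m = V.shape[0]
    for _ in range(rounds):
        for i in range(m):
            others = [j for j in range(m) if j != i]
            base = V[others[0]]
            if m > 2:
                span = (V[others[1:]] - base).T  # (m-1) x (m-2)
                Qf, _ = np.linalg.qr(span)
            else:
                Qf = np.zeros((V.shape[1], 0))
            vi = V[i] - base
            vi_perp = vi - Qf @ (Qf.T @ vi)
            nrm = np.linalg.norm(vi_perp)
            if nrm <= 1e-12:
                continue  # degenerate facet; leave it alone
            outward = -vi_perp / nrm  # away from vertex i
            shift = float(((Y - base) @ outward).max())
            V[others] += shift * outward
    return V


def solve_fractions(K: np.ndarray, X: np.ndarray, p: int = 1) -> np.ndarray:
    """Exact simplex-constrained least squares per point.

    For each point x solves min ||x - K^T f||_2 subject to f >= 0 and
    sum(f) = 1 by enumerating active sets: the optimum restricted to its
    support solves the equality-constrained problem on that support, so for
    the small vertex counts used here the minimum-residual feasible support
    solution is the global optimum.  ``p`` only affects how the objective is
    reported elsewhere; the subproblem itself is the least-squares one.
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, d = K.shape
    n = X.shape[0]
    if X.shape[1] != d:
        raise ValueError(f"points have dimension {X.shape[1]}, vertices {d}")
    F = np.zeros((m, n))
    best = np.full(n, np.inf)
    unresolved = np.ones(n, dtype=bool)

    def try_support(S: tuple[int, ...], mask: np.ndarray) -> None:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return
        r = len(S)
        Ks = K[list(S)]
        A = np.zeros((r + 1, r + 1))
        A[:r, :r] = 2.0 * (Ks @ Ks.T)
        A[:r, r] = 1.0
        A[r, :r] = 1.0
        rhs = np.vstack([2.0 * (Ks @ X[idx].T), np.ones((1, idx.size))])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
        f = sol[:r]  # r x n_idx
        feas = (f >= -1e-12).all(axis=0)
        if not feas.any():
            return
        resid = ((X[idx] - f.T @ Ks) ** 2).sum(axis=1)
        improve = feas & (resid < best[idx] - 1e-15)
        if improve.any():
            rows = idx[improve]
            F[:, rows] = 0.0
            F[np.ix_(list(S), rows)] = f[:, improve]
            best[rows] = resid[improve]

    # the full-support equality solution is a lower bound; where feasible it
    # is optimal, and only boundary points need the subset enumeration
    full_support = tuple(range(m))
    try_support(full_support, unresolved)
    interior = np.isfinite(best)
    unresolved &= ~interior
    if unresolved.any():
        for r in range(m - 1, 0, -1):
            for S in combinations(range(m), r):
                try_support(S, unresolved)
    F = np.clip(F, 0.0, None)
    F /= F.sum(axis=0, keepdims=True)
    return F


def _mst_edges(K: np.ndarray) -> list[tuple[int, int, float]]:
    """Prim's algorithm on the complete Euclidean graph; handles zero-length
    edges (coincident vertices) and breaks ties by lowest vertex index."""
    m = K.shape[0]
    diff = K[:, None, :] - K[None, :, :]
    D = np.sqrt((diff * diff).sum(axis=2))
    visited = np.zeros(m, dtype=bool)
    visited[0] = True
    best_dist = D[0].copy()
    best_from = np.zeros(m, dtype=int)
    edges: list[tuple[int, int, float]] = []
    for _ in range(m - 1):
        cand = np.where(visited, np.inf, best_dist)
        j = int(np.argmin(cand))
        edges.append((int(best_from[j]), j, float(best_dist[j])))
        visited[j] = True
        closer = D[j] < best_dist
        best_dist = np.where(closer, D[j], best_dist)
        best_from = np.where(closer, j, best_from)
    return edges


def mst_length(K: np.ndarray) -> float:
    """Total Euclidean edge length of a minimum spanning tree over vertices."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    if K.shape[0] < 2:
        raise ValueError("MST penalty undefined for fewer than 2 vertices")
    return float(sum(w for _, _, w in _mst_edges(K)))


def simplex_volume(K: np.ndarray) -> float:
    """(m-1)-dimensional volume of the simplex in its own affine span,
    via the Gram determinant; 0 for degenerate vertex sets."""
    K = np.atleast_2d(np.asarray(K, dtype=float))
    m = K.shape[0]
    if m < 2:
        raise ValueError("volume undefined for fewer than 2 vertices")
    W = K[1:] - K[0]
    gram = W @ W.T
    det = float(np.linalg.det(gram))
    if det <= 0:
        return 0.0
    return math.sqrt(det) / math.factorial(m - 1)


def evaluate_objective(
    K: np.ndarray, F: np.ndarray, X: np.ndarray, cfg: ObjectiveConfig
) -> tuple[float, float, float]:
    """Residual + gamma * log-penalty for given vertices and fractions.

    Raises :class:`DegenerateSimplexError` when the penalty base (MST length
    or volume) is exactly zero; during fitting the penalty is floored
    instead (see :func:`fit_simplex`).
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    F = np.atleast_2d(np.asarray(F, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    residual = _residual_term(K, F, X, cfg.p)
    base = mst_length(K) if cfg.penalty == "mst" else simplex_volume(K)
    if base <= 0:
        raise DegenerateSimplexError(
            "penalty base is zero (log -> -inf); use the fitting degeneracy "
            "guard, which floors the penalty"
        )
    penalty = math.log(base)
    return residual + cfg.gamma * penalty, residual, penalty


def _residual_term(K: np.ndarray, F: np.ndarray, X: np.ndarray, p: int) -> float:
    if F.shape[0] != K.shape[0] or F.shape[1] != X.shape[0]:
        raise ValueError("inconsistent shapes for K, F, X")
    R = X - F.T @ K
    if p == 1:
        return float(np.abs(R).sum())
    return float(np.sqrt((R**2).sum(axis=1)).sum())


def _objective_floored(
    K: np.ndarray, F: np.ndarray, X: np.ndarray, cfg: ObjectiveConfig
) -> tuple[float, float, float, bool]:
    residual = _residual_term(K, F, X, cfg.p)
    base = mst_length(K) if cfg.penalty == "mst" else simplex_volume(K)
    floored = base < MST_FLOOR
    penalty = math.log(max(base, MST_FLOOR))
    return residual + cfg.gamma * penalty, residual, penalty, floored


def _logvol_and_grad(K: np.ndarray) -> tuple[float, np.ndarray]:
    m = K.shape[0]
    W = K[1:] - K[0]
    gram = W @ W.T
    sign, logdet = np.linalg.slogdet(gram)
    if sign <= 0 or not np.isfinite(logdet):
        return math.log(MST_FLOOR), np.zeros_like(K)
    logvol = 0.5 * logdet - math.log(math.factorial(m - 1))
    if logvol < math.log(MST_FLOOR):
        return math.log(MST_FLOOR), np.zeros_like(K)
    GW = np.linalg.solve(gram, W)  # d(log vol)/dW
    grad = np.zeros_like(K)
    grad[1:] = GW
    grad[0] = -GW.sum(axis=0)
    return logvol, grad


def _kstep(
    K: np.ndarray,
    F: np.ndarray,
    X: np.ndarray,
    cfg: ObjectiveConfig,
    bounds: list[tuple[float, float]],
) -> np.ndarray:
    m, d = K.shape

    def fun(kflat: np.ndarray) -> tuple[float, np.ndarray]:
        K_ = kflat.reshape(m, d)
        R = X - F.T @ K_
        if cfg.p == 1:
            residual = float(np.abs(R).sum())
            dR = -np.sign(R)
        else:
            norms = np.sqrt((R**2).sum(axis=1))
            residual = float(norms.sum())
            safe = np.where(norms > 1e-12, norms, 1.0)
            dR = -(R / safe[:, None])
            dR[norms <= 1e-12] = 0.0
        grad = F @ dR
        if cfg.penalty == "mst":
            edges = _mst_edges(K_)
            L = sum(w for _, _, w in edges)
            Lf = max(L, MST_FLOOR)
            pen = math.log(Lf)
            gpen = np.zeros_like(K_)
            for a, b, w in edges:
                if w > 1e-12:
                    u = (K_[a] - K_[b]) / w
                    gpen[a] += u
                    gpen[b] -= u
            gpen /= Lf
        else:
            pen, gpen = _logvol_and_grad(K_)
        total = residual + cfg.gamma * pen
        return total, (grad + cfg.gamma * gpen).ravel()

    res = minimize(
        fun,
        K.ravel(),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": cfg.kstep_maxiter},
    )
    return res.x.reshape(m, d)


def fit_simplex(X: np.ndarray, m: int, cfg: ObjectiveConfig | None = None) -> SimplexModel:
    """Alternating F/K optimisation of the regularised simplex objective.

    Starts from :func:`mves_init`; each round solves the fractions exactly
    for the current vertices, then moves the vertices by bounded
    quasi-Newton descent with the fractions held fixed.  Rounds are accepted
    only if they improve the reported objective, so the objective history is
    non-increasing; iteration stops when the improvement drops below
    ``cfg.tol`` (absolute) or ``cfg.rel_tol`` times the objective, or when
    ``cfg.max_iter`` is reached.  Vertex coordinates are
    confined to the data bounding box inflated by ``cfg.bound_inflation``.
    """
    cfg = cfg or ObjectiveConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if m < 2:
        raise ValueError("fitting requires m >= 2 vertices")
    if n < m:
        raise ValueError(f"need at least m={m} points, got {n}")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    lo = lo - cfg.bound_inflation * span
    hi = hi + cfg.bound_inflation * span
    bounds = [(lo[j], hi[j]) for _ in range(m) for j in range(d)]

    K = np.clip(mves_init(X, m, seed=cfg.seed), lo, hi)
    F = solve_fractions(K, X, cfg.p)
    obj, residual, penalty, floored = _objective_floored(K, F, X, cfg)
    history = [obj]
    best = (obj, K, F, residual, penalty, floored)
    converged = False
    n_iter = 0
    for _ in range(cfg.max_iter):
        K_new = _kstep(best[1], F, X, cfg, bounds)
        F_new = solve_fractions(K_new, X, cfg.p)
        obj_new, res_new, pen_new, floored_new = _objective_floored(
            K_new, F_new, X, cfg
        )
        if obj_new >= best[0]:
            # the least-squares F-step does not certify descent of the
            # reported l_p objective; a non-improving round ends the search
            converged = True
            break
        n_iter += 1
        history.append(obj_new)
        improvement = best[0] - obj_new
        best = (obj_new, K_new, F_new, res_new, pen_new, floored_new)
        F = F_new
        if improvement < max(cfg.tol, cfg.rel_tol * abs(obj_new)):
            converged = True
            break
    else:
        if cfg.max_iter > 0:
            warnings.warn("simplex fit hit max_iter without converging")
    obj, K, F, residual, penalty, floored = best
    if floored:
        warnings.warn("final simplex is degenerate (penalty floored)")
        converged = False
    return SimplexModel(
        K=K,
        F=F,
        residual_term=residual,
        penalty_term=penalty,
        objective=obj,
        gamma=cfg.gamma,
        converged=converged,
        n_iter=n_iter,
        objective_history=history[: n_iter + 1],
    )
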