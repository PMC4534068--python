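import itertools
import math

import numpy as np
import pytest

from simplicomplex import (
    DegenerateSimplexError,
    ObjectiveConfig,
    estimate_num_vertices,
    evaluate_objective,
    fit_simplex,
    mst_length,
    mves_init,
    simplex_volume,
    solve_fractions,
)


def spanning_tree_enumeration(K):
    """Independent oracle: minimum spanning tree length by enumerating all
    edge subsets of size m-1 and checking connectivity (m <= 6)."""
    m = len(K)
    edges = [
        (i, j, float(np.linalg.norm(K[i] - K[j])))
        for i in range(m)
        for j in range(i + 1, m)
    ]
    best = math.inf
    for subset in itertools.combinations(edges, m - 1):
        parent = list(range(m))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        ok = True
        for i, j, _ in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w for _, _, w in subset))
    return best


class TestEstimateNumVertices:
    def test_line_segment_gives_two(self, rng):
        t = rng.uniform(size=50)
        pts = np.outer(t, [1.0, 2.0, -1.0])
        assert estimate_num_vertices(pts) == 2

    def test_filled_triangle_gives_three(self, rng):
        w = rng.dirichlet(np.ones(3), size=100)
        verts = np.array([[0, 0, 0], [1, 0, 0.5], [0, 1, -0.5]], dtype=float)
        pts = w @ verts
        assert estimate_num_vertices(pts) == 3

    def test_tetrahedron_cluster_gives_four(self, rng):
        w = rng.dirichlet(np.ones(4), size=200)
        verts = rng.normal(size=(4, 10)) * 5
        pts = w @ verts
        assert estimate_num_vertices(pts, threshold=0.05) == 4

    def test_degenerate_cluster_warns_m1(self):
        pts = np.ones((5, 3))
        with pytest.warns(UserWarning):
            assert estimate_num_vertices(pts) == 1


class TestMvesInit:
    def test_triangle_corners_recovered_exactly(self):
        corners = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        pts = np.vstack([corners, corners, corners])  # satisfies n >= m
        K0 = mves_init(pts, 3)
        # up to vertex order
        d = np.linalg.norm(K0[:, None] - corners[None], axis=2)
        assert d.min(axis=1).max() < 1e-8

    def test_uniform_segment_endpoints(self, rng):
        t = rng.uniform(size=300)
        pts = t[:, None] * np.array([[1.0]])
        K0 = np.sort(mves_init(pts, 2).ravel())
        assert abs(K0[0] - 0.0) < 0.05
        assert abs(K0[1] - 1.0) < 0.05

    def test_collinear_points_reject_m3(self, rng):
        pts = np.outer(rng.uniform(size=20), [1.0, 1.0])
        with pytest.raises(ValueError, match="dimension"):
            mves_init(pts, 3)

    def test_near_enclosure_postcondition(self, rng):
        # noiseless points in a triangle: induced fractions reconstruct
        # nearly every point exactly
        w = rng.dirichlet(np.ones(3), size=200)
        verts = rng.normal(size=(3, 6)) * 3
        pts = w @ verts
        K0 = mves_init(pts, 3)
        F = solve_fractions(K0, pts)
        resid = np.abs(pts - F.T @ K0).sum(axis=1)
        assert (resid > 1e-6).mean() <= 0.05


class TestSolveFractions:
    def test_vertex_maps_to_unit_vector(self):
        K = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        F = solve_fractions(K, K[[1]])
        np.testing.assert_allclose(F[:, 0], [0, 1, 0], atol=1e-10)

    def test_barycentric_example(self):
        K = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        F = solve_fractions(K, np.array([[0.25, 0.25]]))
        np.testing.assert_allclose(F[:, 0], [0.5, 0.25, 0.25], atol=1e-8)

    def test_point_outside_clamps_to_nearest_vertex(self):
        K = np.array([[0.0], [1.0]])
        F = solve_fractions(K, np.array([[-1.0]]))
        np.testing.assert_allclose(F[:, 0], [1.0, 0.0], atol=1e-10)
        resid = abs(-1.0 - (F[:, 0] @ K.ravel()))
        assert resid == pytest.approx(1.0)

    @pytest.mark.parametrize("m,d", [(2, 1), (3, 2)])
    def test_beats_dense_grid_oracle(self, m, d, rng):
        K = rng.normal(size=(m, d)) * 2
        X = rng.normal(size=(25, d))
        F = solve_fractions(K, X)
        solver_resid = ((X - F.T @ K) ** 2).sum(axis=1)
        # grid over the simplex, step 0.01
        g = np.arange(0, 1.0001, 0.01)
        if m == 2:
            W = np.column_stack([g, 1 - g])
        else:
            pairs = [(a, b) for a in g for b in g if a + b <= 1.0 + 1e-12]
            W = np.array([[a, b, 1 - a - b] for a, b in pairs])
        grid_best = ((X[:, None, :] - (W @ K)[None]) ** 2).sum(axis=2).min(axis=1)
        assert (solver_resid <= grid_best + 1e-3).all()

    def test_columns_on_simplex(self, rng):
        K = rng.normal(size=(4, 3))
        F = solve_fractions(K, rng.normal(size=(50, 3)) * 3)
        assert (F >= 0).all()
        np.testing.assert_allclose(F.sum(axis=0), 1.0, atol=1e-9)


class TestMstLength:
    def test_unit_right_triangle(self):
        K = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert mst_length(K) == pytest.approx(2.0)

    def test_coincident_vertices_zero_edge(self):
        K = np.array([[0.0], [0.0], [1.0]])
        assert mst_length(K) == pytest.approx(1.0)

    def test_collinear_points(self):
        K = np.array([[0.0], [1.0], [3.0]])
        assert mst_length(K) == pytest.approx(3.0)

    @pytest.mark.parametrize("m", [3, 4, 5])
    def test_matches_enumeration_oracle(self, m, rng):
        K = rng.normal(size=(m, 3))
        assert mst_length(K) == pytest.approx(spanning_tree_enumeration(K), abs=1e-10)

    def test_single_vertex_errors(self):
        with pytest.raises(ValueError):
            mst_length(np.array([[0.0, 0.0]]))


class TestSimplexVolume:
    def test_unit_right_triangle_area(self):
        K = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert simplex_volume(K) == pytest.approx(0.5)

    def test_segment_length(self):
        assert simplex_volume(np.array([[0.0], [1.0]])) == pytest.approx(1.0)

    def test_degenerate_is_zero(self):
        K = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        assert simplex_volume(K) == 0.0


class TestEvaluateObjective:
    def test_zero_residual_triangle_mst(self):
        K = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        X = K.copy()
        F = np.eye(3)
        cfg = ObjectiveConfig(gamma=10.0)
        obj, resid, pen = evaluate_objective(K, F, X, cfg)
        assert resid == pytest.approx(0.0, abs=1e-12)
        assert obj == pytest.approx(10 * math.log(2.0))

    def test_gamma_zero_equals_residual(self, rng):
        K = rng.normal(size=(3, 2))
        X = rng.normal(size=(10, 2))
        F = solve_fractions(K, X)
        cfg = ObjectiveConfig(gamma=0.0)
        obj, resid, _ = evaluate_objective(K, F, X, cfg)
        assert obj == pytest.approx(resid)

    def test_volume_penalty_variant(self):
        K = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        F = np.eye(3)
        cfg = ObjectiveConfig(gamma=1.0, penalty="volume")
        obj, resid, pen = evaluate_objective(K, F, K, cfg)
        assert pen == pytest.approx(math.log(0.5))
        assert obj == pytest.approx(resid + math.log(0.5))

    def test_degenerate_penalty_raises(self):
        K = np.zeros((2, 2))
        F = np.full((2, 1), 0.5)
        X = np.zeros((1, 2))
        with pytest.raises(DegenerateSimplexError):
            evaluate_objective(K, F, X, ObjectiveConfig())


class TestFitSimplex:
    def test_segment_with_endpoints_zero_objective(self, rng):
        t = np.concatenate([[0.0, 1.0], rng.uniform(size=100)])
        X = t[:, None] * np.array([[2.0, 1.0]])
        cfg = ObjectiveConfig(gamma=0.0)
        model = fit_simplex(X, 2, cfg)
        assert model.residual_term == pytest.approx(0.0, abs=1e-6)

    def test_max_iter_zero_returns_init(self, rng):
        w = rng.dirichlet(np.ones(3), size=60)
        verts = rng.normal(size=(3, 4)) * 2
        X = w @ verts
        cfg = ObjectiveConfig(max_iter=0)
        model = fit_simplex(X, 3, cfg)
        K0 = mves_init(X, 3, seed=cfg.seed)
        lo = X.min(axis=0) - 0.2 * np.maximum(X.max(axis=0) - X.min(axis=0), 1e-6)
        hi = X.max(axis=0) + 0.2 * np.maximum(X.max(axis=0) - X.min(axis=0), 1e-6)
        np.testing.assert_allclose(model.K, np.clip(K0, lo, hi), atol=1e-12)
        assert model.n_iter == 0

    def test_objective_history_nonincreasing(self, rng):
        w = rng.dirichlet(np.ones(3), size=120)
        verts = rng.normal(size=(3, 5)) * 3
        X = w @ verts + rng.normal(size=(120, 5)) * 0.05
        model = fit_simplex(X, 3, ObjectiveConfig())
        h = model.objective_history
        assert all(a >= b - 1e-8 for a, b in zip(h, h[1:]))

    def test_shrinkage_monotone_in_gamma(self, rng):
        t = rng.uniform(size=150)
        X = t[:, None] * np.array([[3.0]])
        lengths = []
        for gamma in [0.0, 2.0, 10.0, 50.0]:
            model = fit_simplex(X, 2, ObjectiveConfig(gamma=gamma))
            lengths.append(mst_length(model.K))
        assert all(a >= b - 1e-6 for a, b in zip(lengths, lengths[1:]))

    def test_penalties_commensurable_across_clusters(self, rng):
        # log-length penalties from two separately fitted clusters can be
        # summed into one complex-level score
        w = rng.dirichlet(np.ones(3), size=80)
        X1 = w @ (rng.normal(size=(3, 4)) * 3)
        t = rng.uniform(size=80)
        X2 = t[:, None] * rng.normal(size=(1, 4)) * 5 + 10
        m1 = fit_simplex(X1, 3, ObjectiveConfig())
        m2 = fit_simplex(X2, 2, ObjectiveConfig())
        total = m1.penalty_term + m2.penalty_term
        assert np.isfinite(total)

    def test_deterministic_given_seed(self, rng):
        w = rng.dirichlet(np.ones(3), size=70)
        X = w @ (rng.normal(size=(3, 4)) * 2) + rng.normal(size=(70, 4)) * 0.02
        m1 = fit_simplex(X, 3, ObjectiveConfig(seed=4))
        m2 = fit_simplex(X, 3, ObjectiveConfig(seed=4))
        np.testing.assert_array_equal(m1.K, m2.K)
        np.testing.assert_array_equal(m1.F, m2.F)

    def test_noiseless_triangle_vertices_recovered(self, triangle_cluster):
        em, truth = triangle_cluster
        from simplicomplex import pca_reduce, zscore_rows

        Z = zscore_rows(em)
        red = pca_reduce(Z, 5)
        model = fit_simplex(red.coords, 3, ObjectiveConfig())
        # true vertices mapped into the same reduced space
        mu = em.values.mean(axis=1)
        sd = em.values.std(axis=1, ddof=1)
        pos = {g: i for i, g in enumerate(em.gene_ids)}
        idx = [pos[g] for g in Z.gene_ids]
        Cz = (truth.C_true[:, idx] - mu[idx]) / sd[idx]
        Kt = (Cz - red.offset) @ red.basis.T
        d = np.linalg.norm(model.K[:, None] - Kt[None], axis=2)
        scale = np.linalg.norm(red.coords.max(axis=0) - red.coords.min(axis=0))
        # each recovered vertex close to a distinct true vertex
        assert sorted(d.argmin(axis=1).tolist()) == [0, 1, 2]
        assert (d.min(axis=1) < 0.05 * scale).all()
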