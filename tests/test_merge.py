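import itertools

import numpy as np
import pytest

from simplicomplex import (
    BootstrapEnsemble,
    ObjectiveConfig,
    SimplicialComplex,
    bootstrap_fit,
    build_complex,
    match_vertex_sets,
    phylogeny_mst,
    should_merge,
)


def brute_force_matching(ref_K, other_K):
    """Oracle: enumerate all permutations, pick minimum total cost."""
    m = len(ref_K)
    best, best_perm = np.inf, None
    for perm in itertools.permutations(range(m)):
        cost = sum(
            np.linalg.norm(ref_K[i] - other_K[perm[i]]) for i in range(m)
        )
        if cost < best:
            best, best_perm = cost, perm
    return np.array(best_perm)


def make_ensemble(means, sd, B=3):
    """Ensemble stub with prescribed vertex means and scalar sds."""
    means = np.asarray(means, dtype=float)
    return BootstrapEnsemble(
        replicate_K=[means.copy() for _ in range(B)],
        vertex_mean=means,
        vertex_sd=np.asarray(sd, dtype=float),
        B=B,
    )


class TestMatchVertexSets:
    def test_recovers_shuffle(self, rng):
        ref = rng.normal(size=(5, 3))
        perm = rng.permutation(5)
        got = match_vertex_sets(ref, ref[perm])
        np.testing.assert_array_equal(ref[perm][got], ref)

    def test_two_by_two_cost_case(self):
        # costs a-x=1, a-y=10, b-x=10, b-y=1: must match a-x, b-y
        ref = np.array([[0.0], [11.0]])
        other = np.array([[1.0], [10.0]])
        perm = match_vertex_sets(ref, other)
        np.testing.assert_array_equal(perm, [0, 1])

    def test_single_vertex_identity(self):
        perm = match_vertex_sets(np.array([[1.0, 2.0]]), np.array([[5.0, 5.0]]))
        np.testing.assert_array_equal(perm, [0])

    def test_unequal_counts_error(self):
        with pytest.raises(ValueError):
            match_vertex_sets(np.zeros((2, 2)), np.zeros((3, 2)))

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_matches_permutation_enumeration(self, m, rng):
        ref = rng.normal(size=(m, 3))
        other = rng.normal(size=(m, 3))
        got = match_vertex_sets(ref, other)
        oracle = brute_force_matching(ref, other)
        got_cost = sum(np.linalg.norm(ref[i] - other[got[i]]) for i in range(m))
        oracle_cost = sum(
            np.linalg.norm(ref[i] - other[oracle[i]]) for i in range(m)
        )
        assert got_cost == pytest.approx(oracle_cost, abs=1e-10)


class TestShouldMerge:
    def test_within_summed_sd(self):
        assert should_merge(np.array([0.0]), 0.6, np.array([1.0]), 0.5)

    def test_beyond_summed_sd(self):
        assert not should_merge(np.array([0.0]), 0.5, np.array([2.0]), 0.5)

    def test_identical_zero_sd_boundary(self):
        v = np.array([1.0, 2.0])
        assert should_merge(v, 0.0, v.copy(), 0.0)

    def test_symmetric(self, rng):
        v1, v2 = rng.normal(size=(2, 4))
        assert should_merge(v1, 0.7, v2, 0.4) == should_merge(v2, 0.4, v1, 0.7)


class TestBootstrapFit:
    def test_zero_noise_triangle_low_sd(self, triangle_cluster):
        from simplicomplex import pca_reduce, zscore_rows

        em, _ = triangle_cluster
        red = pca_reduce(zscore_rows(em), 5)
        ens = bootstrap_fit(red.coords, 3, ObjectiveConfig(), B=10, seed=3)
        scale = np.linalg.norm(red.coords.max(axis=0) - red.coords.min(axis=0))
        assert (ens.vertex_sd < 0.05 * scale).all()

    def test_b1_errors(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.raises(ValueError):
            bootstrap_fit(X, 2, B=1, seed=0)

    def test_deterministic(self, rng):
        w = rng.dirichlet(np.ones(3), size=60)
        X = w @ (rng.normal(size=(3, 4)) * 3)
        e1 = bootstrap_fit(X, 3, ObjectiveConfig(), B=4, seed=9)
        e2 = bootstrap_fit(X, 3, ObjectiveConfig(), B=4, seed=9)
        np.testing.assert_array_equal(e1.vertex_mean, e2.vertex_mean)
        np.testing.assert_array_equal(e1.vertex_sd, e2.vertex_sd)

    def test_replicates_aligned_to_first(self, rng):
        w = rng.dirichlet(np.ones(3), size=80)
        X = w @ (rng.normal(size=(3, 5)) * 4)
        ens = bootstrap_fit(X, 3, ObjectiveConfig(), B=5, seed=2)
        ref = ens.replicate_K[0]
        for Kb in ens.replicate_K[1:]:
            # aligned: identity permutation is optimal
            np.testing.assert_array_equal(match_vertex_sets(ref, Kb), [0, 1, 2])


class TestBuildComplex:
    def test_two_triangles_share_one_vertex(self):
        # nearest cross pair within summed sd -> 5 merged vertices,
        # two 3-sets sharing one index
        t1 = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        t2 = np.array([[0.4, 0.0], [-10.0, 0.0], [0.0, -10.0]])
        cx = build_complex(
            [make_ensemble(t1, [0.3, 0.3, 0.3]), make_ensemble(t2, [0.3, 0.3, 0.3])]
        )
        assert cx.n_vertices == 5
        shared = set(cx.subsimplices[0]) & set(cx.subsimplices[1])
        assert len(shared) == 1
        np.testing.assert_allclose(cx.vertices[list(shared)[0]], [0.2, 0.0])
        assert cx.merge_map[(0, 0)] == cx.merge_map[(1, 0)]

    def test_two_triangles_share_edge(self):
        t1 = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 10.0]])
        t2 = np.array([[0.2, 0.1], [10.1, -0.2], [5.0, -10.0]])
        cx = build_complex(
            [make_ensemble(t1, [0.5, 0.5, 0.1]), make_ensemble(t2, [0.5, 0.5, 0.1])]
        )
        assert cx.n_vertices == 4
        shared = set(cx.subsimplices[0]) & set(cx.subsimplices[1])
        assert len(shared) == 2

    def test_disjoint_union_preserved(self):
        t1 = np.array([[0.0, 0.0], [10.0, 0.0]])
        t2 = np.array([[100.0, 0.0], [110.0, 0.0]])
        cx = build_complex(
            [make_ensemble(t1, [0.1, 0.1]), make_ensemble(t2, [0.1, 0.1])]
        )
        assert cx.n_vertices == 4
        assert not (set(cx.subsimplices[0]) & set(cx.subsimplices[1]))

    def test_merged_sd_is_max_of_members(self):
        t1 = np.array([[0.0, 0.0], [10.0, 0.0]])
        t2 = np.array([[0.5, 0.0], [10.0, 5.0]])
        cx = build_complex(
            [make_ensemble(t1, [0.4, 0.1]), make_ensemble(t2, [0.3, 0.1])]
        )
        shared = cx.merge_map[(0, 0)]
        assert cx.vertex_sd[shared] == pytest.approx(0.4)

    def test_order_invariance_of_positions(self, rng):
        t1 = rng.normal(size=(3, 4))
        t2 = t1 + rng.normal(size=(3, 4)) * 0.01
        e1 = make_ensemble(t1, [1.0, 1.0, 1.0])
        e2 = make_ensemble(t2, [1.0, 1.0, 1.0])
        cx12 = build_complex([e1, e2])
        cx21 = build_complex([e2, e1])
        p1 = np.array(sorted(cx12.vertices.tolist()))
        p2 = np.array(sorted(cx21.vertices.tolist()))
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_collapsed_subsimplex_warns(self):
        t1 = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="collapsed"):
            cx = build_complex([make_ensemble(t1, [2.0, 2.0])])
        assert cx.n_vertices == 1

    def test_merge_map_total_and_single_valued(self):
        t1 = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        t2 = np.array([[0.1, 0.0], [-10.0, 0.0], [0.0, -10.0]])
        cx = build_complex(
            [make_ensemble(t1, [0.2] * 3), make_ensemble(t2, [0.2] * 3)]
        )
        keys = set(cx.merge_map)
        assert keys == {(c, v) for c in range(2) for v in range(3)}
        assert all(0 <= t < cx.n_vertices for t in cx.merge_map.values())


class TestPhylogenyMst:
    def test_line_points_path_edges(self):
        cx = SimplicialComplex(
            vertices=np.array([[0.0], [1.0], [3.0]]),
            vertex_sd=np.zeros(3),
            subsimplices=[[0, 1, 2]],
            merge_map={(0, i): i for i in range(3)},
        )
        tree = phylogeny_mst(cx)
        edges = {(a, b) for a, b, _ in tree.edges}
        assert edges == {(0, 1), (1, 2)}

    def test_two_vertices_single_edge(self):
        cx = SimplicialComplex(
            vertices=np.array([[0.0, 0.0], [3.0, 4.0]]),
            vertex_sd=np.zeros(2),
            subsimplices=[[0, 1]],
            merge_map={(0, 0): 0, (0, 1): 1},
        )
        tree = phylogeny_mst(cx)
        assert tree.edges == [(0, 1, 5.0)]

    def test_single_vertex_tree(self):
        cx = SimplicialComplex(
            vertices=np.array([[0.0]]),
            vertex_sd=np.zeros(1),
            subsimplices=[[0]],
            merge_map={(0, 0): 0},
        )
        tree = phylogeny_mst(cx)
        assert tree.nodes == [0] and tree.edges == []
        assert tree.to_newick() == "v0;"

    def test_newick_roots_at_highest_degree(self):
        # star: vertex 0 connects to 1,2,3
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        cx = SimplicialComplex(
            vertices=pts,
            vertex_sd=np.zeros(4),
            subsimplices=[[0, 1, 2, 3]],
            merge_map={(0, i): i for i in range(4)},
        )
        nwk = phylogeny_mst(cx).to_newick()
        assert nwk.endswith("v0;")
        assert nwk.count(",") == 2

    def test_newick_parses_with_biopython(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        cx = SimplicialComplex(
            vertices=pts,
            vertex_sd=np.zeros(4),
            subsimplices=[[0, 1, 2, 3]],
            merge_map={(0, i): i for i in range(4)},
        )
        nwk = phylogeny_mst(cx).to_newick()
        tree = Phylo.read(StringIO(nwk), "newick")
        assert tree.count_terminals() >= 2
        total = sum(c.branch_length for c in tree.find_clades() if c.branch_length)
        assert total == pytest.approx(7.0)
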