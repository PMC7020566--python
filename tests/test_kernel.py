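import itertools

import numpy as np
import pytest

from bnclust import (
    KrylovCovariance,
    extract_subnetworks,
    krylov_covariance,
    normalize_similarity,
    pair_similarity,
    structure_similarity_matrix,
    subnetwork_kernel,
)
from conftest import path_tree, random_tree, star_tree, tree_from_edges
from oracles import naive_subnetwork_kernel

RIDGE = 1e-6


class TestExtractSubnetworks:
    def test_star_center_radius_one_is_whole_star(self):
        subs = extract_subnetworks(star_tree(5), node_index=0, h=1)
        assert subs.node_sets[0] == (0, 1, 2, 3, 4)
        assert subs.adjacencies[0].sum() == 2 * 4

    def test_path_endpoint_nested_balls(self):
        subs = extract_subnetworks(path_tree(5), node_index=0, h=2)
        assert subs.node_sets == ((0, 1), (0, 1, 2))

    def test_ball_saturates_at_diameter(self, rng):
        tree = random_tree(9, rng)
        subs = extract_subnetworks(tree, node_index=3, h=9)
        assert subs.node_sets[-1] == tuple(range(9))
        np.testing.assert_array_equal(subs.adjacencies[-1], tree.adjacency)

    def test_node_sets_are_nested(self, rng):
        tree = random_tree(11, rng)
        for node in range(11):
            subs = extract_subnetworks(tree, node, h=4)
            for j in range(3):
                assert set(subs.node_sets[j]) <= set(subs.node_sets[j + 1])
                assert node in subs.node_sets[j]

    def test_rejects_nonpositive_radius(self, rng):
        with pytest.raises(ValueError, match="h must be >= 1"):
            extract_subnetworks(random_tree(5, rng), 0, h=0)


class TestKrylovCovariance:
    def test_single_edge_gives_ridge_identity(self):
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        cov = krylov_covariance(adj, d=3, ridge=RIDGE)
        np.testing.assert_allclose(cov.matrix, RIDGE * np.eye(3), atol=1e-15)

    def test_regular_graph_gives_ridge_identity(self):
        # 4-cycle is 2-regular: every power vector is constant
        adj = np.array(
            [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]],
            dtype=float,
        )
        cov = krylov_covariance(adj, d=2, ridge=0.5)
        np.testing.assert_allclose(cov.matrix, 0.5 * np.eye(2), atol=1e-15)

    def test_path_graph_matches_stepwise_computation(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        e = np.ones(3)
        w1 = adj @ e                      # (1, 2, 1)
        u1 = 3 * w1 / np.abs(w1).sum()
        w2 = adj @ w1                     # (2, 2, 2)
        u2 = 3 * w2 / np.abs(w2).sum()
        expected = np.empty((2, 2))
        for a, x in enumerate((u1, u2)):
            for b, y in enumerate((u1, u2)):
                expected[a, b] = np.sum(
                    (x - x.mean()) * (y - y.mean())
                ) / 2
        expected += RIDGE * np.eye(2)
        cov = krylov_covariance(adj, d=2, ridge=RIDGE)
        np.testing.assert_allclose(cov.matrix, expected, atol=1e-12)

    def test_rejects_bad_inputs(self):
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="d must be >= 1"):
            krylov_covariance(adj, d=0)
        with pytest.raises(ValueError, match="at least 2 nodes"):
            krylov_covariance(np.zeros((1, 1)), d=2)
        with pytest.raises(ValueError, match="power vector vanished"):
            krylov_covariance(np.zeros((3, 3)), d=2)


class TestPairSimilarity:
    def test_identity_descriptors_score_one(self):
        c = KrylovCovariance(matrix=np.eye(3), d=3)
        assert pair_similarity(c, c) == pytest.approx(1.0)

    def test_self_similarity_is_root_determinant_as_printed(self, rng):
        a = rng.standard_normal((3, 3))
        mat = a @ a.T + 0.5 * np.eye(3)
        c = KrylovCovariance(matrix=mat, d=3)
        assert pair_similarity(c, c, "as_printed") == pytest.approx(
            np.sqrt(np.linalg.det(mat)), rel=1e-10
        )
        assert pair_similarity(c, c, "s_divergence") == pytest.approx(1.0)

    def test_matches_independent_logdet_evaluation(self, rng):
        a = rng.standard_normal((3, 3))
        b = rng.standard_normal((3, 3))
        cg = KrylovCovariance(matrix=a @ a.T + np.eye(3), d=3)
        ch = KrylovCovariance(matrix=b @ b.T + np.eye(3), d=3)
        avg = (cg.matrix + ch.matrix) / 2
        expected = np.exp(
            -0.5 * (
                np.log(np.linalg.det(avg))
                - np.log(np.linalg.det(cg.matrix))
                - np.log(np.linalg.det(ch.matrix))
            )
        )
        assert pair_similarity(cg, ch) == pytest.approx(expected, rel=1e-10)
        assert pair_similarity(cg, ch) == pytest.approx(
            pair_similarity(ch, cg)
        )

    def test_rejects_non_positive_definite(self):
        bad = KrylovCovariance(matrix=np.diag([1.0, -1.0]), d=2)
        good = KrylovCovariance(matrix=np.eye(2), d=2)
        with pytest.raises(ValueError, match="ridge"):
            pair_similarity(bad, good)


class TestSubnetworkKernel:
    def test_symmetric_in_arguments(self, rng):
        g = random_tree(9, rng)
        h = random_tree(9, rng)
        assert subnetwork_kernel(g, h, h=2, d=2) == pytest.approx(
            subnetwork_kernel(h, g, h=2, d=2), rel=1e-12
        )

    def test_identical_two_node_trees_with_unit_ridge(self):
        # single-edge trees are 1-regular: descriptors are exactly
        # ridge * I, so with ridge = 1 every g equals 1 and k = 1
        t = tree_from_edges(2, [(0, 1)])
        assert subnetwork_kernel(t, t, h=2, d=2, ridge=1.0) == pytest.approx(
            1.0
        )

    @pytest.mark.parametrize("pair_seed", range(10))
    def test_matches_naive_loop_oracle(self, pair_seed):
        rng = np.random.default_rng(500 + pair_seed)
        n = int(rng.integers(5, 13))
        h = int(rng.integers(1, 4))
        d = int(rng.integers(1, 4))
        g = random_tree(n, rng)
        t = random_tree(n, rng)
        for variant in ("as_printed", "s_divergence"):
            expected = naive_subnetwork_kernel(
                g.adjacency, t.adjacency, h=h, d=d, ridge=RIDGE,
                variant=variant,
            )
            assert subnetwork_kernel(
                g, t, h=h, d=d, ridge=RIDGE, variant=variant
            ) == pytest.approx(expected, abs=1e-10)

    def test_rejects_mismatched_node_sets(self, rng):
        with pytest.raises(ValueError, match="node count and node ordering"):
            subnetwork_kernel(random_tree(6, rng), random_tree(7, rng), 1, 1)

    def test_weighted_subgraphs_use_edge_weights(self, rng):
        from bnclust import TreeNetwork

        g = random_tree(8, rng)
        t = random_tree(8, rng)
        base = subnetwork_kernel(g, t, h=2, d=2)

        def with_weights(tree, weight_of):
            return TreeNetwork(
                nodes=tree.nodes, edges=tree.edges,
                adjacency=tree.adjacency,
                edge_weights={e: weight_of(e) for e in tree.edges},
            )

        # unit weights reproduce the binary kernel exactly
        g1 = with_weights(g, lambda e: 1.0)
        t1 = with_weights(t, lambda e: 1.0)
        assert subnetwork_kernel(
            g1, t1, h=2, d=2, subgraph_weights="weighted"
        ) == pytest.approx(base, rel=1e-12)

        # non-uniform weights change the descriptors
        g2 = with_weights(g, lambda e: 0.2 + 0.1 * e[0])
        t2 = with_weights(t, lambda e: 0.9 - 0.05 * e[1])
        assert subnetwork_kernel(
            g2, t2, h=2, d=2, subgraph_weights="weighted"
        ) != pytest.approx(base, rel=1e-6)

        with pytest.raises(ValueError, match="edge weights"):
            subnetwork_kernel(g, t, h=2, d=2, subgraph_weights="weighted")


class TestNormalizeSimilarity:
    def test_rank_one_matrix_normalizes_to_ones(self):
        out = normalize_similarity(np.array([[4.0, 2.0], [2.0, 1.0]]))
        np.testing.assert_allclose(out, np.ones((2, 2)), atol=1e-12)

    def test_unit_diagonal_matrix_unchanged(self, rng):
        m = rng.uniform(0, 1, size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        np.testing.assert_allclose(normalize_similarity(m), m, atol=1e-12)

    def test_scales_by_root_self_similarities(self):
        out = normalize_similarity(np.array([[2.0, 1.0], [1.0, 2.0]]))
        np.testing.assert_allclose(
            out, np.array([[1.0, 0.5], [0.5, 1.0]]), atol=1e-12
        )

    def test_rejects_nonpositive_diagonal(self):
        with pytest.raises(ValueError, match="index"):
            normalize_similarity(np.array([[0.0, 1.0], [1.0, 2.0]]))


class TestStructureSimilarityMatrix:
    def test_single_network(self, rng):
        out = structure_similarity_matrix([random_tree(6, rng)], h=2, d=2)
        np.testing.assert_allclose(out, [[1.0]], atol=1e-12)

    def test_duplicated_network_fully_similar(self, rng):
        tree = random_tree(8, rng)
        out = structure_similarity_matrix([tree, tree], h=2, d=2)
        np.testing.assert_allclose(out, np.ones((2, 2)), atol=1e-10)

    @pytest.mark.parametrize("variant", ["as_printed", "s_divergence"])
    def test_matches_normalized_pairwise_kernels(self, rng, variant):
        trees = [random_tree(7, rng) for _ in range(3)]
        out = structure_similarity_matrix(
            trees, h=2, d=2, variant=variant
        )
        raw = np.empty((3, 3))
        for a in range(3):
            for b in range(3):
                raw[a, b] = subnetwork_kernel(
                    trees[a], trees[b], h=2, d=2, variant=variant
                )
        expected = raw / np.sqrt(np.outer(np.diag(raw), np.diag(raw)))
        np.testing.assert_allclose(out, expected, atol=1e-10)

    @pytest.mark.parametrize("variant", ["as_printed", "s_divergence"])
    def test_entries_in_unit_interval(self, variant):
        rng = np.random.default_rng(99)
        trees = [random_tree(10, rng) for _ in range(8)]
        out = structure_similarity_matrix(trees, h=3, d=3, variant=variant)
        assert np.all(out > 0) and np.all(out <= 1)
        np.testing.assert_allclose(np.diag(out), 1.0, atol=1e-12)
        np.testing.assert_allclose(out, out.T, atol=1e-12)

    def test_invariant_under_common_node_relabeling(self, rng):
        n = 9
        g = random_tree(n, rng)
        t = random_tree(n, rng)
        perm = rng.permutation(n)
        relabeled = []
        for tree in (g, t):
            edges = frozenset(
                (min(perm[i], perm[j]), max(perm[i], perm[j]))
                for i, j in tree.edges
            )
            adj = np.zeros((n, n))
            for i, j in edges:
                adj[i, j] = adj[j, i] = 1.0
            relabeled.append(
                tree_from_edges(n, edges)
            )
        before = structure_similarity_matrix([g, t], h=2, d=2)
        after = structure_similarity_matrix(relabeled, h=2, d=2)
        assert after[0, 1] == pytest.approx(before[0, 1], abs=1e-10)
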