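"""Modularity, simulated annealing, graph kernels, kernel k-means and SOM."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import coexnet as cx
from coexnet.clustering import (
    KernelMatrix,
    Partition,
    kernel_kmeans,
    kernel_som,
    modularity_pairwise,
)
from coexnet.network import GeneNetwork

from conftest import graph_from_nx, random_connected_graph, two_cliques


def random_partition(nodes, k, rng) -> Partition:
    labels = rng.integers(0, k, size=len(nodes))
    return Partition.from_labels(list(nodes), labels)


class TestModularity:
    def test_single_cluster_gives_zero(self):
        rng = np.random.default_rng(0)
        G = random_connected_graph(8, rng)
        P = Partition.from_labels(G.nodes, [1] * 8)
        assert cx.modularity(G, P) == pytest.approx(0.0, abs=1e-14)

    def test_two_disjoint_triangles_give_half(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        G = graph_from_nx(g)
        P = Partition.from_labels(G.nodes, [1, 1, 1, 2, 2, 2])
        assert cx.modularity(G, P) == pytest.approx(0.5, abs=1e-14)

    def test_both_algebraic_forms_agree(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            G = random_connected_graph(int(rng.integers(5, 15)), rng)
            P = random_partition(G.nodes, int(rng.integers(2, 5)), rng)
            assert cx.modularity(G, P) == pytest.approx(
                modularity_pairwise(G, P), abs=1e-12
            )

    def test_edgeless_graph_raises(self):
        G = GeneNetwork(["a", "b"])
        P = Partition.from_labels(["a", "b"], [1, 2])
        with pytest.raises(ValueError, match="no edges"):
            cx.modularity(G, P)

    def test_partition_must_cover_nodes(self):
        G = GeneNetwork(["a", "b"], [("a", "b")])
        P = Partition.from_labels(["a"], [1])
        with pytest.raises(ValueError, match="cover"):
            cx.modularity(G, P)


class TestAnnealModularity:
    def test_recovers_two_cliques(self):
        G = two_cliques(5)
        truth = [0] * 5 + [1] * 5
        hits = 0
        for seed in range(20):
            part = cx.anneal_modularity(G, annealing_parameter=100.0, n_sweeps=40, seed=seed)
            labels = part.labels_for(sorted(G.nodes, key=lambda n: int(n)))
            if adjusted_rand_score(truth, labels) == 1.0:
                # the returned Q must equal the planted partition's Q
                planted = Partition.from_labels(
                    sorted(G.nodes, key=lambda n: int(n)), truth
                )
                assert part.modularity == pytest.approx(cx.modularity(G, planted))
                hits += 1
        assert hits >= 19  # >= 0.95 recovery over 20 seeds

    def test_zero_sweeps_returns_random_initialization(self):
        G = two_cliques(4)
        seed = 3
        part = cx.anneal_modularity(G, n_init_clusters=4, n_sweeps=0, seed=seed)
        expected = np.random.default_rng(seed).integers(0, 4, size=G.n_nodes)
        ref = Partition.from_labels(sorted(G.nodes), expected)
        assert part.assignment == ref.assignment

    def test_never_below_initialization_quality(self):
        G = two_cliques(5)
        for seed in range(5):
            init = np.random.default_rng(seed).integers(0, 10, size=G.n_nodes)
            init_part = Partition.from_labels(sorted(G.nodes), init)
            q0 = cx.modularity(G, init_part)
            part = cx.anneal_modularity(G, n_init_clusters=10, n_sweeps=15, seed=seed)
            assert part.modularity >= q0 - 1e-12

    def test_seed_reproducible_and_order_invariant(self):
        G = two_cliques(5)
        a = cx.anneal_modularity(G, n_sweeps=20, seed=4)
        shuffled = GeneNetwork(
            list(reversed(G.nodes)),
            [(u, v) for u, v in G.graph.edges],
        )
        b = cx.anneal_modularity(shuffled, n_sweeps=20, seed=4)
        assert a.assignment == b.assignment

    def test_edgeless_raises(self):
        with pytest.raises(ValueError, match="no edges"):
            cx.anneal_modularity(GeneNetwork(["a", "b", "c"]))


class TestHeatKernel:
    def test_beta_zero_is_identity(self):
        G = two_cliques(3)
        K = cx.heat_kernel(G, 0.0)
        assert np.allclose(K.matrix, np.eye(G.n_nodes))

    def test_large_beta_converges_to_uniform(self):
        rng = np.random.default_rng(2)
        G = random_connected_graph(6, rng)
        K = cx.heat_kernel(G, 100.0)
        assert np.allclose(K.matrix, 1.0 / 6, atol=1e-6)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        for beta in (0.1, 1.0, 10.0):
            G = random_connected_graph(7, rng)
            K = cx.heat_kernel(G, beta)
            assert np.allclose(K.matrix.sum(axis=1), 1.0, atol=1e-10)

    def test_negative_beta_raises(self):
        with pytest.raises(ValueError):
            cx.heat_kernel(two_cliques(3), -1.0)


class TestCommuteTimeKernel:
    def test_pseudo_inverse_identities(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            G = random_connected_graph(7, rng)
            from coexnet.clustering import _laplacian

            L, _ = _laplacian(G)
            K = cx.commute_time_kernel(G).matrix
            assert np.allclose(L @ K @ L, L, atol=1e-8)
            assert np.allclose(K @ L @ K, K, atol=1e-8)

    def test_row_sums_zero(self):
        rng = np.random.default_rng(5)
        G = random_connected_graph(8, rng)
        K = cx.commute_time_kernel(G)
        assert np.allclose(K.matrix.sum(axis=1), 0.0, atol=1e-10)

    def test_path_graph_matches_resistance_distance(self):
        # on a tree the effective resistance between i and j is the path length
        G = graph_from_nx(nx.path_graph(5))
        K = cx.commute_time_kernel(G).matrix
        nodes = sorted(G.nodes)
        for i in range(5):
            for j in range(5):
                a, b = nodes.index(str(i)), nodes.index(str(j))
                r = K[a, a] + K[b, b] - 2 * K[a, b]
                assert r == pytest.approx(abs(i - j), abs=1e-8)

    def test_disconnected_raises(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        with pytest.raises(ValueError, match="component"):
            cx.commute_time_kernel(graph_from_nx(g))


def block_kernel(sizes, values=(1.0, 0.0)):
    """Block-constant PSD kernel: within-block value 1, across 0."""
    n = sum(sizes)
    K = np.zeros((n, n))
    start = 0
    for s in sizes:
        K[start : start + s, start : start + s] = values[0]
        start += s
    ids = [f"n{i:02d}" for i in range(n)]
    return KernelMatrix(matrix=K, kernel_name="heat", node_ids=ids, parameter=None)


class TestKernelKMeans:
    def test_k_one_single_cluster(self):
        K = block_kernel([4, 4])
        part = kernel_kmeans(K, k=1, seed=0)
        assert part.n_clusters == 1

    def test_two_block_kernel_exact_recovery(self):
        K = block_kernel([5, 3])
        part = kernel_kmeans(K, k=2, n_restarts=5, seed=1)
        labels = [part.assignment[n] for n in K.node_ids]
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_duplicate_rows_co_cluster(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((5, 3))
        A[4] = A[0]  # duplicate feature rows -> identical kernel rows
        K = KernelMatrix(A @ A.T, "heat", [f"n{i}" for i in range(5)])
        part = kernel_kmeans(K, k=2, n_restarts=5, seed=2)
        assert part.assignment["n0"] == part.assignment["n4"]

    def test_k_larger_than_p_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            kernel_kmeans(block_kernel([2, 2]), k=5)

    def test_seed_reproducible(self):
        K = block_kernel([4, 4, 4])
        a = kernel_kmeans(K, 3, seed=7)
        b = kernel_kmeans(K, 3, seed=7)
        assert a.assignment == b.assignment


class TestKernelSOM:
    def test_one_by_one_grid_single_cluster(self):
        part = kernel_som(block_kernel([3, 3]), 1, 1, seed=0)
        assert part.n_clusters == 1

    def test_two_block_kernel_recovery_on_2x1_grid(self):
        K = block_kernel([6, 4])
        part = kernel_som(K, 2, 1, n_epochs=20, seed=1)
        labels = [part.assignment[n] for n in K.node_ids]
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_radius_zero_coincides_with_kernel_kmeans(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((8, 4))
        K = KernelMatrix(A @ A.T, "heat", [f"n{i}" for i in range(8)])
        som = kernel_som(K, 2, 2, n_epochs=25, seed=3, initial_radius=0.0)
        # neighbourhood-free batch SOM is batch kernel k-means: its final
        # assignment must be a fixed point of the k-means update
        members = {}
        for n, lab in som.assignment.items():
            members.setdefault(lab, []).append(K.node_ids.index(n))
        from coexnet.clustering import _kernel_distances

        dist = _kernel_distances(K.matrix, [np.array(v) for v in members.values()])
        reassign = np.argmin(dist, axis=1)
        lab_order = list(members)
        for i, n in enumerate(K.node_ids):
            assert lab_order[reassign[i]] == som.assignment[n]

    def test_grid_larger_than_nodes_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            kernel_som(block_kernel([2, 2]), 3, 3)


class TestSelectBestPartition:
    def test_single_candidate_returned(self):
        G = two_cliques(3)
        part = Partition.from_labels(sorted(G.nodes), [1, 1, 1, 2, 2, 2])
        assert cx.select_best_partition(G, [part]) is part

    def test_argmax_by_modularity(self):
        G = two_cliques(3)
        good = Partition.from_labels(sorted(G.nodes), [1, 1, 1, 2, 2, 2], method="a")
        bad = Partition.from_labels(sorted(G.nodes), [1, 2, 1, 2, 1, 2], method="b")
        best = cx.select_best_partition(G, [bad, good])
        assert best is good

    def test_tie_break_by_method_name(self):
        G = two_cliques(3)
        p1 = Partition.from_labels(sorted(G.nodes), [1, 1, 1, 2, 2, 2], method="zeta")
        p2 = Partition.from_labels(sorted(G.nodes), [1, 1, 1, 2, 2, 2], method="alpha")
        assert cx.select_best_partition(G, [p1, p2]) is p2

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="no candidate"):
            cx.select_best_partition(two_cliques(3), [])


class TestKernelMatrixInvariants:
    def test_kernels_are_psd_and_symmetric(self):
        rng = np.random.default_rng(9)
        G = random_connected_graph(8, rng)
        for K in (cx.heat_kernel(G, 1.0), cx.commute_time_kernel(G)):
            assert np.allclose(K.matrix, K.matrix.T)
            assert np.linalg.eigvalsh(K.matrix).min() >= -1e-8

    def test_non_psd_rejected(self):
        bad = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="PSD"):
            KernelMatrix(bad, "heat", ["a", "b"])
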