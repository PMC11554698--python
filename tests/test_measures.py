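"""Local graph measures: hand-worked examples, algebraic identities, oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assortnet import (
    Connectome,
    betweenness_centrality,
    binarize,
    clustering_coefficient,
    global_assortativity,
    nodal_assortativity,
    node_degree,
    node_strength,
)
from assortnet.exceptions import InvalidParameterError, NoEdgesError

from conftest import random_connectome


def net_from_edges(n, edges, weights=None, modality="structural"):
    A = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        A[i, j] = A[j, i] = w
    return Connectome(A, modality=modality)


STAR3 = net_from_edges(4, [(0, 1), (0, 2), (0, 3)])
STAR4 = net_from_edges(5, [(0, i) for i in range(1, 5)])
PATH4 = net_from_edges(4, [(0, 1), (1, 2), (2, 3)])
CYCLE4 = net_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
TRIANGLE = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])


class TestBinarize:
    def test_indicator_with_negative_weights(self):
        net = net_from_edges(3, [(0, 1), (1, 2)], weights=[0.5, -0.3], modality="functional")
        B = binarize(net, 0.0).adjacency
        assert B[0, 1] == 1 and B[1, 2] == 1 and B[0, 2] == 0

    def test_threshold_cuts_small_weights(self):
        net = net_from_edges(4, [(0, 1), (1, 2), (2, 3)], weights=[2, 5, 7])
        B = binarize(net, 4).adjacency
        assert B[0, 1] == 0 and B[1, 2] == 1 and B[2, 3] == 1

    def test_empty_graph_fixed_point(self):
        net = Connectome(np.zeros((3, 3)))
        assert not binarize(net, 1.0).adjacency.any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(InvalidParameterError):
            binarize(TRIANGLE, -0.1)


class TestGlobalAssortativity:
    def test_star_is_perfectly_disassortative(self):
        assert global_assortativity(STAR3) == pytest.approx(-1.0)

    def test_path_hand_value(self):
        # degrees 1,2,2,1; Pearson over the 6 directed degree pairs = -0.5
        assert global_assortativity(PATH4) == pytest.approx(-0.5)

    def test_regular_graph_is_nan(self):
        assert np.isnan(global_assortativity(CYCLE4))

    def test_edgeless_network_raises(self):
        with pytest.raises(NoEdgesError):
            global_assortativity(Connectome(np.zeros((4, 4))))

    def test_matches_directed_edgelist_pearson_and_networkx(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            net = random_connectome(rng, n=int(rng.integers(4, 30)), p=0.3)
            r = global_assortativity(net)
            B = (np.abs(net.adjacency) > 0).astype(int)
            d = B.sum(1)
            ii, jj = np.nonzero(np.triu(B, 1))
            x = np.concatenate([d[ii], d[jj]]).astype(float)
            y = np.concatenate([d[jj], d[ii]]).astype(float)
            if x.var() == 0:
                assert np.isnan(r)
                continue
            oracle = np.corrcoef(x, y)[0, 1]
            assert r == pytest.approx(oracle, abs=1e-9)
            G = nx.from_numpy_array(B)
            assert r == pytest.approx(nx.degree_assortativity_coefficient(G), abs=1e-9)


class TestNodalAssortativity:
    def test_star_hand_values(self):
        # m=4: delta_i = 2 for all, deltabar = 1/4, r = -1 -> r_i = -1/4
        vec = nodal_assortativity(STAR3)
        assert vec.extras["delta"] == pytest.approx([2, 2, 2, 2])
        assert vec.extras["deltabar"] == pytest.approx([0.25] * 4)
        assert vec.values == pytest.approx([-0.25] * 4)
        assert vec.values.sum() == pytest.approx(-1.0)

    def test_regular_graph_degenerate_convention(self):
        vec = nodal_assortativity(CYCLE4)
        assert vec.degenerate
        assert np.isnan(vec.values).all()
        assert vec.extras["deltabar"] == pytest.approx([0.25] * 4)

    def test_isolated_node_stays_in_vector(self):
        net = net_from_edges(5, [(0, 1), (0, 2), (0, 3)])  # node 4 isolated
        vec = nodal_assortativity(net)
        assert len(vec) == 5
        assert vec.extras["delta"][4] == 0.0
        assert vec.values.sum() == pytest.approx(vec.extras["r"], abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_decomposition_identities(self, seed):
        rng = np.random.default_rng(seed)
        net = random_connectome(rng, n=int(rng.integers(4, 25)), p=0.35)
        vec = nodal_assortativity(net)
        assert vec.extras["deltabar"].sum() == pytest.approx(1.0, abs=1e-12)
        r = vec.extras["r"]
        m = net.node_count
        if not vec.degenerate and np.isfinite(r):
            assert vec.values.sum() == pytest.approx(r, abs=1e-9)
            assert np.all(vec.values <= (r + 1) / m + 1e-12)
            assert np.all((vec.values >= -1 - 1e-12) & (vec.values <= 1 + 1e-12))

    def test_weighted_mode_uses_strengths(self):
        net = net_from_edges(3, [(0, 1), (1, 2)], weights=[0.5, 2.0])
        vec = nodal_assortativity(net, degree_mode="weighted")
        # strengths: 0.5, 2.5, 2.0 -> disparity from strengths, not counts
        assert vec.extras["delta"][0] == pytest.approx(2.0 / 0.5)


def brute_force_cc(B):
    n = B.shape[0]
    out = np.zeros(n)
    for v in range(n):
        neigh = np.nonzero(B[v])[0]
        d = len(neigh)
        if d < 2:
            continue
        tri = sum(B[i, j] for i, j in itertools.combinations(neigh, 2))
        out[v] = 2 * tri / (d * (d - 1))
    return out


def brute_force_bc(B):
    """Exhaustive shortest-path counting (BFS distances + DFS enumeration)."""
    n = B.shape[0]
    adj = [np.nonzero(B[i])[0].tolist() for i in range(n)]

    def bfs_dist(s):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        return dist

    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        dist = bfs_dist(s)
        if t not in dist:
            continue
        target = dist[t]
        paths = []

        def dfs(u, path):
            if len(path) - 1 > target:
                return
            if u == t:
                if len(path) - 1 == target:
                    paths.append(list(path))
                return
            for w in adj[u]:
                if w not in path:
                    path.append(w)
                    dfs(w, path)
                    path.pop()

        dfs(s, [s])
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / sigma
    return out


class TestClusteringCoefficient:
    def test_complete_graph(self):
        assert clustering_coefficient(TRIANGLE).values == pytest.approx([1, 1, 1])

    def test_star_has_no_triangles(self):
        assert clustering_coefficient(STAR4).values == pytest.approx([0] * 5)

    def test_matches_triangle_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            net = random_connectome(rng, n=5, p=0.5, weighted=False)
            B = net.adjacency
            assert clustering_coefficient(net).values == pytest.approx(brute_force_cc(B))


class TestBetweennessCentrality:
    def test_path_midpoint(self):
        net = net_from_edges(3, [(0, 1), (1, 2)])
        assert betweenness_centrality(net).values == pytest.approx([0, 1, 0])

    def test_star_centers(self):
        # center of K_{1,k} carries all C(k,2) leaf pairs
        assert betweenness_centrality(STAR3).values[0] == pytest.approx(3.0)
        assert betweenness_centrality(STAR4).values[0] == pytest.approx(6.0)

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            net = random_connectome(rng, n=6, p=0.4, weighted=False)
            assert betweenness_centrality(net).values == pytest.approx(
                brute_force_bc(net.adjacency))


class TestStrengthAndDegree:
    def test_signed_weights(self):
        net = net_from_edges(3, [(0, 1), (0, 2)], weights=[0.5, -0.3], modality="functional")
        assert node_strength(net).values[0] == pytest.approx(0.8)
        assert node_degree(net).values[0] == 2

    def test_isolated_node(self):
        net = net_from_edges(3, [(0, 1)])
        assert node_strength(net).values[2] == 0
        assert node_degree(net).values[2] == 0

    def test_binary_graph_identity(self):
        net = net_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert node_strength(net).values == pytest.approx(node_degree(net).values)


class TestRelabelingEquivariance:
    @pytest.mark.parametrize("measure_fn", [
        nodal_assortativity, clustering_coefficient, betweenness_centrality,
        node_strength, node_degree,
    ])
    def test_permutation(self, measure_fn):
        rng = np.random.default_rng(21)
        net = random_connectome(rng, n=12, p=0.3)
        perm = rng.permutation(12)
        permuted = Connectome(net.adjacency[np.ix_(perm, perm)], net.modality)
        a = measure_fn(net).values[perm]
        b = measure_fn(permuted).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_global_assortativity_invariant(self):
        rng = np.random.default_rng(22)
        net = random_connectome(rng, n=12, p=0.3)
        perm = rng.permutation(12)
        permuted = Connectome(net.adjacency[np.ix_(perm, perm)], net.modality)
        assert global_assortativity(net) == pytest.approx(global_assortativity(permuted))
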