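import itertools

import networkx as nx
import numpy as np
import pytest

from ecolandnet.centrality import (
    betweenness_centrality,
    centrality_report,
    closeness_centrality,
    degree_centrality,
    network_density,
)
from ecolandnet.gravity import TieNetwork


def net_from(A, cities=None):
    A = np.asarray(A, dtype=int)
    if cities is None:
        cities = [f"C{i:02d}" for i in range(A.shape[0])]
    return TieNetwork(cities=cities, A=A, threshold_used=0.0)


def star(n=5):
    A = np.zeros((n, n), dtype=int)
    A[0, 1:] = 1
    A[1:, 0] = 1
    return net_from(A)


def random_net(rng, n, p=0.3):
    A = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(A, 0)
    return net_from(A)


class TestDensity:
    def test_complete_directed_three_nodes(self):
        A = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        s = network_density(net_from(A))
        assert (s.m, s.density) == (6, 1.0)

    def test_empty_network(self):
        s = network_density(net_from(np.zeros((4, 4))))
        assert s.density == 0.0

    def test_arithmetic_47_413(self):
        rng = np.random.default_rng(0)
        A = np.zeros((47, 47), dtype=int)
        off = np.argwhere(~np.eye(47, dtype=bool))
        picks = rng.choice(len(off), size=413, replace=False)
        A[off[picks, 0], off[picks, 1]] = 1
        s = network_density(net_from(A))
        assert s.m == 413
        assert round(s.density, 3) == 0.191

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            network_density(net_from(np.zeros((1, 1))))


class TestDegree:
    def test_star_center_maximal(self):
        deg = degree_centrality(star(5))
        assert deg[0] == 1.0
        np.testing.assert_allclose(deg[1:], 0.25)

    def test_isolated_node_zero(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = 1
        assert degree_centrality(net_from(A))[3] == 0.0

    def test_either_direction_counts(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = 1  # one-way tie still links the pair
        deg = degree_centrality(net_from(A))
        assert deg[0] == deg[1] == 0.5

    def test_in_out_modes(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[0, 2] = 1
        assert degree_centrality(net_from(A), mode="out")[0] == 1.0
        assert degree_centrality(net_from(A), mode="in")[0] == 0.0

    def test_oracle_equivalence_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            net = random_net(rng, 10)
            g = nx.from_numpy_array(((net.A + net.A.T) > 0).astype(int))
            ours = degree_centrality(net)
            theirs = np.array([nx.degree_centrality(g)[i] for i in range(10)])
            np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestBetweenness:
    def test_star_center_one_leaves_zero(self):
        bc = betweenness_centrality(star(5))
        assert bc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_oracle_equivalence_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 13))
            net = random_net(rng, n)
            g = nx.from_numpy_array(((net.A + net.A.T) > 0).astype(int))
            ours = betweenness_centrality(net)
            theirs = nx.betweenness_centrality(g, normalized=True)
            np.testing.assert_allclose(
                ours, [theirs[i] for i in range(n)], atol=1e-10)

    def test_brute_force_path_enumeration_small(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = 7
            net = random_net(rng, n, p=0.35)
            A = ((net.A + net.A.T) > 0).astype(int)
            g = nx.from_numpy_array(A)
            raw = np.zeros(n)
            for j, k in itertools.combinations(range(n), 2):
                try:
                    paths = list(nx.all_shortest_paths(g, j, k))
                except nx.NetworkXNoPath:
                    continue
                for i in range(n):
                    if i in (j, k):
                        continue
                    raw[i] += sum(i in p for p in paths) / len(paths)
            ours = betweenness_centrality(net, normalized=False)
            np.testing.assert_allclose(ours, raw, atol=1e-10)


class TestCloseness:
    def test_star_center(self):
        clo, far = closeness_centrality(star(5))
        assert far[0] == 4.0
        assert clo[0] == 1.0

    def test_disconnected_dyads_unreachable_convention(self):
        # two disjoint pairs on n=4: farness = 1 + 2 unreachable * n(=4) = 9
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        clo, far = closeness_centrality(net_from(A))
        np.testing.assert_allclose(far, 9.0)
        np.testing.assert_allclose(clo, 3 / 9)

    def test_oracle_equivalence_connected_graphs(self):
        rng = np.random.default_rng(13)
        done = 0
        while done < 100:
            net = random_net(rng, 9, p=0.4)
            g = nx.from_numpy_array(((net.A + net.A.T) > 0).astype(int))
            if not nx.is_connected(g):
                continue
            ours, _ = closeness_centrality(net)
            theirs = nx.closeness_centrality(g)
            np.testing.assert_allclose(
                ours, [theirs[i] for i in range(9)], atol=1e-10)
            done += 1


class TestReport:
    def test_star_center_ranks_first_everywhere(self):
        rep = centrality_report(star(5))
        center = rep[rep.city_id == "C00"].iloc[0]
        assert (center["degree_rank"], center["closeness_rank"],
                center["betweenness_rank"]) == (1, 1, 1)

    def test_regular_graph_lexicographic_tie_break(self):
        A = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        rep = centrality_report(net_from(A))
        nodes = rep[rep.city_id != "Average"]
        assert list(nodes.sort_values("degree_rank").city_id) == sorted(
            nodes.city_id)

    def test_mean_row_present_and_in_range(self):
        rng = np.random.default_rng(3)
        rep = centrality_report(random_net(rng, 20, 0.2))
        mean = rep[rep.city_id == "Average"].iloc[0]
        assert 0 <= mean["degree_pct"] <= 100
        assert len(rep) == 21

    def test_adding_tie_never_decreases_degree(self):
        rng = np.random.default_rng(5)
        net = random_net(rng, 8, 0.3)
        before = degree_centrality(net)
        A2 = net.A.copy()
        zeros = np.argwhere((A2 == 0) & ~np.eye(8, dtype=bool))
        i, j = zeros[0]
        A2[i, j] = 1
        after = degree_centrality(net_from(A2))
        assert (after >= before - 1e-12).all()
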