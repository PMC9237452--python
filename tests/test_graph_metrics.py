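import networkx as nx
import numpy as np
import pytest

from cycleconn.graph_metrics import (
    GraphMetricError,
    binary_cpl,
    find_unreachable_nodes,
    modularity_q,
    system_segregation,
    weighted_cpl,
)
from cycleconn.static_fc import BinaryAdjacency, FCMatrix, ZMatrix


def _graph(adj):
    adj = np.asarray(adj, dtype=np.int8)
    e = adj.shape[0] * (adj.shape[0] - 1) / 2
    return BinaryAdjacency(adj, density=adj.sum() / 2 / e,
                           density_actual=adj.sum() / 2 / e)


def brute_modularity(adj, part):
    """Literal evaluation of Q = Σ_c [e_c/m − (d_c/2m)²]."""
    m = adj.sum() / 2
    q = 0.0
    for c in set(part):
        nodes = [i for i in range(len(part)) if part[i] == c]
        e_c = sum(adj[i][j] for i in nodes for j in nodes if i < j)
        d_c = sum(adj[i][j] for i in nodes for j in range(len(part)))
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def floyd_warshall_hops(adj):
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


class TestModularity:
    def test_single_community_is_zero(self):
        adj = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
        assert modularity_q(_graph(adj), [0] * 5) == pytest.approx(0.0, abs=1e-15)

    def test_two_triangles_with_bridge(self):
        adj = np.zeros((6, 6), dtype=int)
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
            adj[i, j] = adj[j, i] = 1
        q = modularity_q(_graph(adj), [0, 0, 0, 1, 1, 1])
        assert q == pytest.approx(5 / 14, abs=1e-12)

    def test_k4_split_into_pairs(self):
        adj = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        assert modularity_q(_graph(adj), [0, 0, 1, 1]) == pytest.approx(-1 / 6,
                                                                       abs=1e-12)

    def test_empty_graph_is_error(self):
        with pytest.raises(GraphMetricError, match="empty"):
            modularity_q(_graph(np.zeros((3, 3))), [0, 1, 0])

    def test_agrees_with_networkx(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(20, 0.3, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            adj = nx.to_numpy_array(g, dtype=int)
            part = rng.integers(0, 3, size=20)
            communities = [set(np.flatnonzero(part == c)) for c in range(3)]
            communities = [c for c in communities if c]
            expected = nx.community.modularity(g, communities)
            assert modularity_q(_graph(adj), part) == pytest.approx(expected,
                                                                    abs=1e-12)


class TestSystemSegregation:
    def test_equal_means_give_zero_and_zero_between_gives_one(self):
        # 4 parcels, two systems of 2
        z = np.zeros((4, 4))
        z[0, 1] = z[1, 0] = 0.5   # within system A
        z[2, 3] = z[3, 2] = 0.5   # within system B
        part = [0, 0, 1, 1]
        assert system_segregation(ZMatrix(z), part) == pytest.approx(1.0)
        z[np.ix_([0, 1], [2, 3])] = 0.5
        z[np.ix_([2, 3], [0, 1])] = 0.5
        assert system_segregation(ZMatrix(z), part) == pytest.approx(0.0)

    def test_direct_arithmetic_example(self):
        # within z {0.8, 0.6}, between {0.2, 0.15}: SS = (0.7−0.175)/0.7
        z = np.zeros((4, 4))
        z[0, 1] = z[1, 0] = 0.8
        z[2, 3] = z[3, 2] = 0.6
        z[0, 2] = z[2, 0] = 0.2
        z[1, 3] = z[3, 1] = 0.15
        z[0, 3] = z[3, 0] = 0.2
        z[1, 2] = z[2, 1] = 0.15
        ss = system_segregation(ZMatrix(z), [0, 0, 1, 1])
        assert ss == pytest.approx((0.7 - 0.175) / 0.7, abs=1e-12)

    def test_invariant_to_global_positive_rescaling(self, rng):
        z = rng.normal(size=(8, 8))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        part = rng.integers(0, 3, size=8)
        a = system_segregation(ZMatrix(z), part)
        b = system_segregation(ZMatrix(4.2 * z), part)
        assert a == pytest.approx(b, abs=1e-12)

    def test_increases_as_between_coupling_drops(self):
        from cycleconn.synthetic import plant_block_fc
        from cycleconn.static_fc import FCMatrix, fisher_r2z

        part = [0] * 5 + [1] * 5
        values = []
        for r_b in (0.3, 0.2, 0.1, 0.0):
            z = fisher_r2z(FCMatrix(plant_block_fc(10, [5, 5], 0.5, r_b)))
            values.append(system_segregation(z, part))
        assert np.all(np.diff(values) > 0)


class TestWeightedCPL:
    def test_complete_graph_uniform_r(self):
        values = np.full((6, 6), 0.5)
        np.fill_diagonal(values, 1.0)
        res = weighted_cpl(FCMatrix(values))
        assert res.value == pytest.approx(0.5, abs=1e-12)
        assert res.n_excluded_pairs == 0

    def test_three_node_detour(self):
        values = np.array([
            [1.0, 0.9, 0.05],
            [0.9, 1.0, 0.9],
            [0.05, 0.9, 1.0],
        ])
        res = weighted_cpl(FCMatrix(values))
        # d(1,3) = min(0.95, 0.1+0.1) = 0.2
        assert res.value == pytest.approx((0.1 + 0.1 + 0.2) / 3, abs=1e-12)

    def test_all_r_near_one_gives_near_zero(self):
        values = np.full((5, 5), 1.0 - 1e-9)
        np.fill_diagonal(values, 1.0)
        assert weighted_cpl(FCMatrix(values)).value == pytest.approx(0.0, abs=1e-6)

    def test_negative_edges_excluded_and_flagged(self):
        values = np.array([
            [1.0, 0.5, -0.4],
            [0.5, 1.0, -0.4],
            [-0.4, -0.4, 1.0],
        ])
        res = weighted_cpl(FCMatrix(values))
        # node 2 unreachable: 4 ordered pairs excluded
        assert res.n_excluded_pairs == 4
        assert res.value == pytest.approx(0.5)


class TestBinaryCPL:
    def test_complete_graph_and_cycle_and_path(self):
        complete = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
        assert binary_cpl(_graph(complete)) == pytest.approx(1.0)
        cycle = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            cycle[i, j] = cycle[j, i] = 1
        assert binary_cpl(_graph(cycle)) == pytest.approx(4 / 3, abs=1e-12)
        path = np.zeros((3, 3), dtype=int)
        for i, j in [(0, 1), (1, 2)]:
            path[i, j] = path[j, i] = 1
        assert binary_cpl(_graph(path)) == pytest.approx(4 / 3, abs=1e-12)

    def test_disconnected_error_lists_nodes(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        adj[2, 3] = adj[3, 2] = 1
        with pytest.raises(GraphMetricError, match=r"\[2, 3\]"):
            binary_cpl(_graph(adj))

    def test_exclusion_repairs_connectivity(self):
        adj = np.zeros((5, 5), dtype=int)
        for i, j in [(0, 1), (1, 2), (2, 0)]:
            adj[i, j] = adj[j, i] = 1
        adj[3, 4] = adj[4, 3] = 1
        assert binary_cpl(_graph(adj), exclude=[3, 4]) == pytest.approx(1.0)

    def test_non_increasing_in_density(self, rng):
        values = np.corrcoef(rng.normal(size=(60, 15)), rowvar=False)
        from cycleconn.static_fc import binarize_by_density

        previous = np.inf
        for density in (0.3, 0.5, 0.8, 1.0):
            g = binarize_by_density(FCMatrix(values), density)
            try:
                cpl = binary_cpl(g)
            except GraphMetricError:
                continue
            assert cpl <= previous + 1e-12
            previous = cpl


class TestFindUnreachableNodes:
    def test_all_connected_gives_empty(self):
        adj = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        assert find_unreachable_nodes([_graph(adj)]).parcels == []

    def test_isolated_node_reported_with_context(self):
        connected = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        isolated = connected.copy()
        isolated[3, :] = isolated[:, 3] = 0
        report = find_unreachable_nodes(
            [_graph(connected), _graph(isolated)], labels=["s@0.25", "s@0.10"]
        )
        assert report.parcels == [3]
        assert report.occurrences[3] == ["s@0.10"]


def test_oracle_agreement_on_random_graphs(rng):
    """modularity and bCPL match independent brute-force implementations."""
    for _ in range(25):
        p = int(rng.integers(6, 25))
        adj = (rng.random((p, p)) < 0.4).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        # force connectivity with a ring
        for i in range(p):
            adj[i, (i + 1) % p] = adj[(i + 1) % p, i] = 1
        part = rng.integers(0, 4, size=p)
        g = _graph(adj)
        assert modularity_q(g, part) == pytest.approx(
            brute_modularity(adj, part), abs=1e-12
        )
        dist = floyd_warshall_hops(adj)
        expected = dist[~np.eye(p, dtype=bool)].mean()
        assert binary_cpl(g) == pytest.approx(expected, abs=1e-12)
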