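import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mantanet.netbuild import (MovementNetwork, build_network, edge_density,
                               hop_distance_matrix, network_metrics,
                               node_centralities,
                               subnetwork_by_tagging_region)
from mantanet.published import NETWORK_METRICS

from conftest import ts


def stations_frame(ids, region="R"):
    return pd.DataFrame([dict(station_id=s, name=s, region=region,
                              lat=float(i) * 0.1, lon=130.0 + i * 0.1)
                         for i, s in enumerate(ids)])


def movements_frame(pairs, tid="T1"):
    return pd.DataFrame([dict(transmitter_id=tid, from_station=a,
                              to_station=b, depart=ts(i), arrive=ts(i + 1),
                              duration_min=1.0)
                         for i, (a, b) in enumerate(pairs)])


def net_from_edges(edges, nodes):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, count=1, weight=1.0 / len(edges))
    return MovementNetwork(graph=g, n_movements=len(edges))


def floyd_warshall(adj):
    """Independent all-pairs shortest-path oracle (hop counts)."""
    n = adj.shape[0]
    dist = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def brute_force_betweenness(g):
    """Path-enumeration oracle: even split over all shortest paths."""
    btw = {v: 0.0 for v in g.nodes}
    for s in g.nodes:
        for t in g.nodes:
            if s == t:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    btw[v] += 1.0 / len(paths)
    return btw


def random_digraph(rng, n, p):
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for a in range(n):
        for b in range(n):
            if a != b and rng.random() < p:
                g.add_edge(a, b, count=1, weight=1.0)
    return g


class TestBuildNetwork:
    def test_counts_and_weights(self):
        st = stations_frame(["A", "B", "C"])
        net = build_network(movements_frame([("A", "B"), ("A", "B"),
                                             ("B", "A")]), st)
        assert net.graph["A"]["B"]["count"] == 2
        assert net.graph["B"]["A"]["count"] == 1
        assert net.graph["A"]["B"]["weight"] == pytest.approx(2 / 3)
        assert net.graph["B"]["A"]["weight"] == pytest.approx(1 / 3)
        # node set is the full station table, including unused C
        assert set(net.nodes) == {"A", "B", "C"}
        assert sum(d["weight"] for *_, d in net.graph.edges(data=True)) \
            == pytest.approx(1.0)

    def test_zero_movements_gives_edgeless_network(self):
        st = stations_frame(["A", "B"])
        net = build_network(movements_frame([]), st)
        assert net.n_edges == 0 and set(net.nodes) == {"A", "B"}

    def test_unknown_station_rejected(self):
        st = stations_frame(["A", "B"])
        with pytest.raises(KeyError, match="Z"):
            build_network(movements_frame([("A", "Z")]), st)

    def test_simulated_edge_counts_match_truth(self, small_sim_tables):
        from mantanet.events import extract_movements, extract_residence_events
        detections, _, stations, truth = small_sim_tables
        mv = extract_movements(extract_residence_events(detections))
        net = build_network(mv, stations)
        want = truth.true_movements.groupby(
            ["from_station", "to_station"]).size()
        for (a, b), c in want.items():
            assert net.graph[a][b]["count"] == c
        assert net.n_edges == len(want)


class TestSubnetworks:
    def _deployments(self):
        return pd.DataFrame([
            dict(transmitter_id="T1", animal_id="M1", sex="F",
                 tagging_region="East", deploy_station="A", deploy_time=ts(0)),
            dict(transmitter_id="T2", animal_id="M2", sex="M",
                 tagging_region="West", deploy_station="C", deploy_time=ts(0)),
        ])

    def test_region_with_no_movements_is_edgeless(self):
        st = stations_frame(["A", "B", "C"])
        mv = movements_frame([("A", "B")], tid="T1")
        net = subnetwork_by_tagging_region(mv, self._deployments(), "West", st)
        assert net.n_edges == 0 and len(net.nodes) == 3

    def test_complete_three_station_region(self):
        # all six ordered pairs present among three stations
        st = stations_frame(["A", "B", "C", "D"])
        pairs = [p for p in itertools.permutations("ABC", 2)]
        net = subnetwork_by_tagging_region(
            movements_frame(pairs, tid="T1"), self._deployments(), "East", st)
        m = network_metrics(net, tagging_region_nodes=3)
        assert m.n_edges == 6
        assert m.n_nodes_connected == 3
        assert m.apl == 1.0 and m.diameter == 1.0

    def test_unknown_region_rejected(self):
        st = stations_frame(["A"])
        with pytest.raises(KeyError, match="Atlantis"):
            subnetwork_by_tagging_region(movements_frame([]),
                                         self._deployments(), "Atlantis", st)

    def test_region_movements_partition_global_total(self, small_sim_tables):
        from mantanet.events import extract_movements, extract_residence_events
        detections, deployments, stations, _ = small_sim_tables
        mv = extract_movements(extract_residence_events(detections))
        total = 0
        for region in deployments["tagging_region"].unique():
            sub = subnetwork_by_tagging_region(mv, deployments, region, stations)
            total += sub.n_movements
        assert total == len(mv)


class TestNetworkMetrics:
    @pytest.mark.parametrize("region,row", sorted(NETWORK_METRICS.items()))
    def test_density_identity_on_published_counts(self, region, row):
        # printed density cells follow from n_edges / (34*33)
        got = edge_density(row["n_nodes"], row["n_edges"])
        assert round(got, 3) == pytest.approx(row["edge_density"], abs=1e-9)

    def test_complete_digraph_k3(self):
        nodes = ["A", "B", "C"]
        net = net_from_edges(list(itertools.permutations(nodes, 2)), nodes)
        m = network_metrics(net)
        assert m.apl == 1.0 and m.diameter == 1.0
        assert m.edge_density == pytest.approx(1.0)

    def test_single_edge_pair_like_wayag(self):
        # 2 connected nodes, 1 edge: reachable-pairs convention gives APL =
        # diameter = 1 even though most pairs are unreachable
        net = net_from_edges([("A", "B")], ["A", "B", "C", "D"])
        m = network_metrics(net)
        assert m.n_nodes_connected == 2
        assert m.apl == 1.0 and m.diameter == 1.0

    def test_edgeless_network_metrics_undefined(self):
        net = net_from_edges([], ["A", "B"])
        net.n_movements = 0
        m = network_metrics(net)
        assert np.isnan(m.apl) and np.isnan(m.diameter)
        assert m.n_edges == 0

    def test_parallel_movements_do_not_change_topology_metrics(self):
        st = stations_frame(["A", "B", "C"])
        base = [("A", "B"), ("B", "C")]
        m1 = network_metrics(build_network(movements_frame(base), st))
        m2 = network_metrics(build_network(
            movements_frame(base + [("A", "B")]), st))
        assert (m1.n_edges, m1.apl, m1.diameter) \
            == (m2.n_edges, m2.apl, m2.diameter)
        assert m2.n_movements == m1.n_movements + 1

    def test_apl_diameter_match_floyd_warshall_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            g = random_digraph(rng, int(rng.integers(3, 11)), 0.3)
            net = MovementNetwork(graph=g, n_movements=g.number_of_edges())
            m = network_metrics(net)
            adj, _ = net.adjacency()
            dist = floyd_warshall(adj)
            off = ~np.eye(len(adj), dtype=bool)
            finite = np.isfinite(dist) & off
            if not finite.any():
                assert np.isnan(m.apl) and np.isnan(m.diameter)
            else:
                assert m.apl == pytest.approx(dist[finite].mean())
                assert m.diameter == pytest.approx(dist[finite].max())

    def test_metrics_invariant_to_node_relabelling(self):
        rng = np.random.default_rng(9)
        g = random_digraph(rng, 8, 0.3)
        net = MovementNetwork(graph=g, n_movements=g.number_of_edges())
        m1 = network_metrics(net)
        mapping = dict(zip(g.nodes, rng.permutation([f"N{i}" for i in range(8)])))
        h = nx.relabel_nodes(g, mapping)
        m2 = network_metrics(MovementNetwork(graph=h,
                                             n_movements=h.number_of_edges()))
        assert m1.to_dict() == m2.to_dict()


class TestHopMatrix:
    def test_matches_networkx_shortest_paths(self):
        rng = np.random.default_rng(17)
        g = random_digraph(rng, 12, 0.2)
        adj = nx.to_numpy_array(g, dtype=bool)
        dist = hop_distance_matrix(adj)
        nxd = dict(nx.all_pairs_shortest_path_length(g))
        nodes = list(g.nodes)
        for i, a in enumerate(nodes):
            for j, b in enumerate(nodes):
                want = nxd[a].get(b, np.inf)
                assert dist[i, j] == want


class TestCentralities:
    def test_complete_digraph_k3_centralities(self):
        nodes = ["A", "B", "C"]
        net = net_from_edges(list(itertools.permutations(nodes, 2)), nodes)
        c = node_centralities(net).set_index("station_id")
        assert (c["in_degree"] == 2).all()
        assert (c["out_degree"] == 2).all()
        assert (c["degree"] == 4).all()
        assert (c["betweenness"] == 0.0).all()
        assert np.allclose(c["eigenvector"], 1.0)

    def test_directed_path_betweenness(self):
        net = net_from_edges([("A", "B"), ("B", "C")], ["A", "B", "C"])
        c = node_centralities(net).set_index("station_id")
        assert c.loc["B", "betweenness"] == 1.0
        assert c.loc["A", "betweenness"] == 0.0
        assert c.loc["C", "betweenness"] == 0.0
        # closeness: A reaches {B:1, C:2} -> 2/3; C reaches nothing -> 0
        assert c.loc["A", "closeness"] == pytest.approx(2 / 3)
        assert c.loc["C", "closeness"] == 0.0

    def test_betweenness_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            g = random_digraph(rng, int(rng.integers(4, 9)), 0.35)
            net = MovementNetwork(graph=g, n_movements=max(g.number_of_edges(), 1))
            c = node_centralities(net).set_index("station_id")["betweenness"]
            want = brute_force_betweenness(g)
            for v in g.nodes:
                assert c[v] == pytest.approx(want[v], abs=1e-9)

    def test_eigenvector_scaled_to_unit_max(self, small_sim_tables):
        from mantanet.events import extract_movements, extract_residence_events
        detections, _, stations, _ = small_sim_tables
        mv = extract_movements(extract_residence_events(detections))
        net = build_network(mv, stations)
        c = node_centralities(net)
        assert c["eigenvector"].max() == pytest.approx(1.0)
        assert (c["eigenvector"] >= 0).all()
        assert (c["degree"] == c["in_degree"] + c["out_degree"]).all()
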