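"""Directed weighted movement networks and their metrics.

Stations are nodes; a directed edge (u, v) exists when at least one movement
u→v was recorded, carries the movement count, and is weighted by the
proportion of all movements in the network. Conventions, fixed across the
package:

* Every network (the archipelago-wide one and each tagging-region one) keeps
  the *full* station set as nodes, so edge density always uses the same
  denominator n·(n−1).
* Path metrics (average path length, diameter) are hop counts on the
  unweighted digraph, averaged/maximised over *reachable* ordered pairs
  only; on an edgeless network they are undefined (NaN), not zero.
* Eigenvector centrality defaults to the symmetrised weighted graph (a
  directed variant is exposed), since the directed version is degenerate for
  nodes without in-edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MovementNetwork",
    "NetworkMetrics",
    "build_network",
    "subnetwork_by_tagging_region",
    "network_metrics",
    "node_centralities",
    "edge_density",
    "hop_distance_matrix",
]


@dataclass
class MovementNetwork:
    """A directed movement network over a fixed station set."""

    graph: nx.DiGraph     # edge attrs: count, weight
    n_movements: int

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_counts(self) -> pd.DataFrame:
        rows = [dict(from_station=u, to_station=v,
                     count=d["count"], weight=d["weight"])
                for u, v, d in self.graph.edges(data=True)]
        return (pd.DataFrame(rows, columns=["from_station", "to_station",
                                            "count", "weight"])
                .sort_values(["from_station", "to_station"])
                .reset_index(drop=True))

    def adjacency(self) -> tuple[np.ndarray, list]:
        """Boolean adjacency matrix and the node order used."""
        order = list(self.graph.nodes)
        idx = {n: i for i, n in enumerate(order)}
        a = np.zeros((len(order), len(order)), dtype=bool)
        for u, v in self.graph.edges:
            a[idx[u], idx[v]] = True
        return a, order


@dataclass
class NetworkMetrics:
    """The eight network-level summary metrics."""

    n_nodes_network: int
    n_nodes_tagging_region: Optional[int]
    n_nodes_connected: int
    n_edges: int
    n_movements: int
    edge_density: float
    apl: float        # NaN when undefined (no edges)
    diameter: float   # NaN when undefined

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def edge_density(n_nodes: int, n_edges: int) -> float:
    """Directed edge density: realised fraction of the n·(n−1) ordered pairs."""
    if n_nodes < 2:
        return float("nan")
    return n_edges / (n_nodes * (n_nodes - 1))


def build_network(movements: pd.DataFrame, stations: pd.DataFrame,
                  node_scope: str = "all_stations") -> MovementNetwork:
    """Aggregate movements into a directed weighted network.

    ``node_scope='all_stations'`` (default) keeps every station as a node
    whether or not it recorded a movement; ``'connected'`` keeps only
    stations incident to at least one movement.
    """
    if node_scope not in ("all_stations", "connected"):
        raise ValueError("node_scope must be 'all_stations' or 'connected'")
    station_ids = list(stations["station_id"])
    known = set(station_ids)
    if len(movements):
        used = set(movements["from_station"]) | set(movements["to_station"])
        unknown = used - known
        if unknown:
            raise KeyError(f"movement references unknown station(s): {sorted(unknown)}")
        if (movements["from_station"] == movements["to_station"]).any():
            raise ValueError("self-movement (from == to) is not a valid movement")
    g = nx.DiGraph()
    if node_scope == "all_stations":
        g.add_nodes_from(station_ids)
    n_total = len(movements)
    if n_total:
        counts = (movements.groupby(["from_station", "to_station"], sort=True)
                  .size())
        for (u, v), c in counts.items():
            g.add_edge(u, v, count=int(c), weight=float(c) / n_total)
    return MovementNetwork(graph=g, n_movements=int(n_total))


def subnetwork_by_tagging_region(movements: pd.DataFrame,
                                 deployments: pd.DataFrame,
                                 region: str,
                                 stations: pd.DataFrame) -> MovementNetwork:
    """Network restricted to movements of animals *tagged* in one region.

    The node set stays the full station table, so densities remain
    comparable across tagging regions.
    """
    regions = set(deployments["tagging_region"]) | set(stations["region"])
    if region not in regions:
        raise KeyError(f"unknown tagging region: {region!r}")
    tids = set(deployments.loc[deployments["tagging_region"] == region,
                               "transmitter_id"])
    sub = movements[movements["transmitter_id"].isin(tids)]
    return build_network(sub, stations)


def hop_distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path hop counts of a digraph (np.inf = unreachable).

    Level-synchronous BFS from all sources at once via boolean matrix
    products; fine for the ≲100-node arrays this package deals with.
    """
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        frontier = (frontier.astype(np.uint8) @ a.astype(np.uint8)) > 0
        frontier &= ~reached
        dist[frontier] = d
        reached |= frontier
    return dist


def _apl_diameter(adj: np.ndarray) -> tuple[float, float]:
    dist = hop_distance_matrix(adj)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(dist) & off
    if not finite.any():
        return float("nan"), float("nan")
    vals = dist[finite]
    return float(vals.mean()), float(vals.max())


def network_metrics(net: MovementNetwork,
                    tagging_region_nodes: Optional[int] = None) -> NetworkMetrics:
    """Compute the eight network-level metrics for one movement network."""
    g = net.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    connected = sum(1 for v in g.nodes
                    if g.in_degree(v) + g.out_degree(v) > 0)
    adj, _ = net.adjacency()
    apl, diam = _apl_diameter(adj) if m else (float("nan"), float("nan"))
    return NetworkMetrics(
        n_nodes_network=n,
        n_nodes_tagging_region=tagging_region_nodes,
        n_nodes_connected=connected,
        n_edges=m,
        n_movements=net.n_movements,
        edge_density=edge_density(n, m),
        apl=apl,
        diameter=diam,
    )


def _closeness(dist: np.ndarray) -> np.ndarray:
    """Inverse mean finite out-distance per node (0 when nothing reachable)."""
    n = dist.shape[0]
    out = np.zeros(n)
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        d = dist[i, off[i]]
        d = d[np.isfinite(d)]
        if d.size:
            out[i] = d.size / d.sum()
    return out


def node_centralities(net: MovementNetwork,
                      eigenvector_mode: str = "symmetrized") -> pd.DataFrame:
    """Six node-level centralities for every node of the network.

    * in/out/total degree count distinct neighbours along incoming and
      outgoing edges (movement multiplicities do not inflate degree);
    * betweenness is the unnormalised count of directed shortest paths
      through a node, split evenly across equal-length alternatives;
    * closeness is the inverse mean hop distance to the node's reachable set
      (0 for sinks that reach nothing);
    * eigenvector centrality is computed on the symmetrised
      movement-count-weighted graph by default (``eigenvector_mode=
      'directed'`` uses the directed graph and may fail to converge on
      graphs with source-only nodes), scaled so the maximum is 1.
    """
    g = net.graph
    order = list(g.nodes)
    if not order:
        raise ValueError("network has no nodes")
    adj, _ = net.adjacency()
    dist = hop_distance_matrix(adj)
    btw = nx.betweenness_centrality(g, normalized=False)
    idx = {v: i for i, v in enumerate(order)}
    W = np.zeros((len(order), len(order)))
    for a, b, d in g.edges(data=True):
        W[idx[a], idx[b]] += d["count"]
    if g.number_of_edges() == 0:
        eigv = np.zeros(len(order))
    elif eigenvector_mode == "symmetrized":
        # leading eigenvector of the symmetrized weight matrix; on a
        # disconnected graph it concentrates on the dominant component
        # (other components score ~0), which is the convention we document
        vals, vecs = np.linalg.eigh(W + W.T)
        eigv = np.abs(vecs[:, int(np.argmax(vals))])
    elif eigenvector_mode == "directed":
        vals, vecs = np.linalg.eig(W)
        eigv = np.abs(vecs[:, int(np.argmax(vals.real))])
    else:
        raise ValueError("eigenvector_mode must be 'symmetrized' or 'directed'")
    if eigv.max() > 0:
        eigv = eigv / eigv.max()
    eigv = np.where(eigv < 1e-12, 0.0, eigv)
    df = pd.DataFrame({
        "station_id": order,
        "in_degree": [g.in_degree(v) for v in order],
        "out_degree": [g.out_degree(v) for v in order],
        "betweenness": [btw[v] for v in order],
        "closeness": _closeness(dist),
        "eigenvector": eigv,
    })
    df.insert(3, "degree", df["in_degree"] + df["out_degree"])
    return df
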