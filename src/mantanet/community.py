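"""Modularity-based community (subpopulation) detection.

The movement network is symmetrised (directed movement counts summed over
both directions) and partitioned to maximise Newman–Girvan weighted
modularity

    Q = Σ_c [ w_c / W − (s_c / 2W)² ],

where W is the total symmetrised edge weight, w_c the weight inside
community c and s_c the total strength of its nodes. Q ≥ 0.3 is
conventionally read as a good division. Stations with no movements at all
are removed before clustering (they carry no information about mixing), as
was done for the two unconnected receivers in the observed array.

Exact maximisation (integer programming via igraph's optimal-modularity
routine) is used up to ``exact_max_nodes`` nodes — comfortably covering a
~32-node receiver array — with multi-restart Louvain plus single-node
refinement as the large-graph fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .netbuild import MovementNetwork

logger = logging.getLogger(__name__)

__all__ = ["CommunityPartition", "modularity", "detect_communities"]


@dataclass
class CommunityPartition:
    membership: dict              # node -> community id (connected nodes only)
    modularity_q: float
    n_communities: int
    method: str                   # 'exact' or 'louvain+refine'
    removed_nodes: list = field(default_factory=list)

    @property
    def good_division(self) -> bool:
        """Q at or above the conventional 0.3 threshold."""
        return self.modularity_q >= 0.3

    def to_dict(self) -> dict:
        return dict(modularity_q=self.modularity_q,
                    n_communities=self.n_communities,
                    method=self.method,
                    good_division=self.good_division,
                    removed_nodes=list(self.removed_nodes))


def _symmetrized(net, weight: str = "count",
                 symmetrize: str = "sum") -> nx.Graph:
    g = net.graph if isinstance(net, MovementNetwork) else net
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    if isinstance(g, nx.DiGraph):
        for u, v, d in g.edges(data=True):
            w = float(d.get(weight, 1.0))
            if und.has_edge(u, v):
                if symmetrize == "sum":
                    und[u][v]["weight"] += w
                else:  # 'max': one direction's count
                    und[u][v]["weight"] = max(und[u][v]["weight"], w)
            else:
                und.add_edge(u, v, weight=w)
    else:
        for u, v, d in g.edges(data=True):
            und.add_edge(u, v, weight=float(d.get(weight, 1.0)))
    return und


def modularity(net, membership: dict, weight: str = "count",
               symmetrize: str = "sum") -> float:
    """Weighted Newman–Girvan modularity of a given partition.

    ``membership`` must assign a community to every node of the (symmetrised)
    graph. Raises on a graph with zero total edge weight.
    """
    und = _symmetrized(net, weight=weight, symmetrize=symmetrize)
    nodes = list(und.nodes)
    missing = [v for v in nodes if v not in membership]
    if missing:
        raise KeyError(f"membership missing node(s): {missing}")
    two_w = sum(d["weight"] for _, _, d in und.edges(data=True)) * 2.0
    if two_w == 0:
        raise ValueError("graph has zero total edge weight")
    strength = {v: 0.0 for v in nodes}
    intra = {}
    for u, v, d in und.edges(data=True):
        w = d["weight"]
        strength[u] += w
        strength[v] += w
        if membership[u] == membership[v]:
            intra[membership[u]] = intra.get(membership[u], 0.0) + w
    comms = set(membership[v] for v in nodes)
    q = 0.0
    W = two_w / 2.0
    for c in comms:
        w_c = intra.get(c, 0.0)
        s_c = sum(strength[v] for v in nodes if membership[v] == c)
        q += w_c / W - (s_c / two_w) ** 2
    return q


def _refine(und: nx.Graph, membership: dict) -> dict:
    """Greedy single-node moves until no move improves Q."""
    memb = dict(membership)
    improved = True
    while improved:
        improved = False
        for v in und.nodes:
            best_c, best_q = memb[v], modularity(und, memb, weight="weight")
            for c in set(memb.values()) - {memb[v]}:
                trial = dict(memb)
                trial[v] = c
                q = modularity(und, trial, weight="weight")
                if q > best_q + 1e-12:
                    best_q, best_c = q, c
            if best_c != memb[v]:
                memb[v] = best_c
                improved = True
    return memb


def _exact_partition(und: nx.Graph) -> dict:
    import igraph as ig

    nodes = list(und.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = [(idx[u], idx[v]) for u, v in und.edges]
    weights = [und[u][v]["weight"] for u, v in und.edges]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    part = g.community_optimal_modularity(weights=weights)
    return {nodes[i]: int(c) for i, c in enumerate(part.membership)}


def _louvain_partition(und: nx.Graph, n_restarts: int, seed) -> dict:
    rng = np.random.default_rng(seed)
    best_q, best = -np.inf, None
    for _ in range(n_restarts):
        s = int(rng.integers(0, 2**31 - 1))
        comms = nx.algorithms.community.louvain_communities(
            und, weight="weight", seed=s)
        memb = {v: i for i, com in enumerate(comms) for v in com}
        memb = _refine(und, memb)
        q = modularity(und, memb, weight="weight")
        if q > best_q:
            best_q, best = q, memb
    return best


def detect_communities(net, method: str = "exact_if_small",
                       exact_max_nodes: int = 40,
                       n_restarts: int = 20,
                       symmetrize: str = "sum",
                       seed=None) -> CommunityPartition:
    """Maximum-modularity partition of the connected part of the network.

    Degree-0 (isolated) nodes are removed first and reported in
    ``removed_nodes``. ``method`` is ``'exact_if_small'`` (default: exact up
    to ``exact_max_nodes`` nodes, Louvain beyond), ``'exact'`` or
    ``'louvain'``. The exact route falls back to Louvain with a warning if
    the solver fails.
    """
    und = _symmetrized(net, weight="count", symmetrize=symmetrize)
    isolated = [v for v in und.nodes if und.degree(v) == 0]
    if isolated:
        logger.info("removed %d unconnected node(s) before clustering: %s",
                    len(isolated), ", ".join(map(str, sorted(isolated))))
        und.remove_nodes_from(isolated)
    if und.number_of_nodes() == 0 or und.number_of_edges() == 0:
        raise ValueError("no connected nodes: nothing to cluster")

    use_exact = (method == "exact"
                 or (method == "exact_if_small"
                     and und.number_of_nodes() <= exact_max_nodes))
    if method not in ("exact", "exact_if_small", "louvain"):
        raise ValueError("method must be 'exact', 'exact_if_small' or 'louvain'")
    if use_exact:
        try:
            memb = _exact_partition(und)
            used = "exact"
        except Exception as exc:  # solver unavailable/failed
            logger.warning("exact modularity solver failed (%s); "
                           "falling back to Louvain", exc)
            memb = _louvain_partition(und, n_restarts, seed)
            used = "louvain+refine"
    else:
        memb = _louvain_partition(und, n_restarts, seed)
        used = "louvain+refine"

    # canonical community ids: 0..k-1 in order of first appearance
    seen = {}
    canon = {}
    for v in und.nodes:
        c = memb[v]
        if c not in seen:
            seen[c] = len(seen)
        canon[v] = seen[c]
    q = modularity(und, canon, weight="weight")
    return CommunityPartition(membership=canon, modularity_q=q,
                              n_communities=len(seen), method=used,
                              removed_nodes=sorted(map(str, isolated)))
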