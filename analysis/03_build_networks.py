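#!/usr/bin/env python
"""Build the movement networks and compute network- and node-level metrics.

One directed weighted network over the full station set, plus one per
tagging region (movements of animals tagged there, same node set so the
densities share a denominator). Writes the metrics table in the layout of
the published study's network-metrics table, the edge list and the six
node centralities under results/networks/.
"""

import sys
from pathlib import Path

import pandas as pd

from mantanet import ingest, netbuild

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "networks"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stations = ingest.read_stations(ROOT / "data" / "stations.csv")
    deployments = ingest.read_deployments(ROOT / "data" / "deployments.csv")
    movements = pd.read_csv(ROOT / "events" / "movements.csv")

    net = netbuild.build_network(movements, stations)
    rows = [dict(network="all",
                 **netbuild.network_metrics(net).to_dict())]
    region_sizes = stations.groupby("region").size()
    for region in sorted(deployments["tagging_region"].unique()):
        sub = netbuild.subnetwork_by_tagging_region(
            movements, deployments, region, stations)
        rows.append(dict(network=region, **netbuild.network_metrics(
            sub, tagging_region_nodes=int(region_sizes[region])).to_dict()))
    metrics = pd.DataFrame(rows)
    metrics.to_csv(OUT / "network_metrics.csv", index=False)

    net.edge_counts().to_csv(OUT / "edges.csv", index=False)
    cent = netbuild.node_centralities(net)
    cent.to_csv(OUT / "centralities.csv", index=False)

    g = metrics.iloc[0]
    hub = cent.sort_values("betweenness", ascending=False).iloc[0]
    print(f"global network : {g.n_nodes_connected}/{g.n_nodes_network} "
          f"connected nodes, {g.n_edges} edges, {g.n_movements} movements")
    print(f"               : density {g.edge_density:.3f}, "
          f"APL {g.apl:.2f}, diameter {g.diameter:.0f}")
    print(f"top hub        : {hub.station_id} "
          f"(betweenness {hub.betweenness:.1f}, degree {hub.degree})")
    print(metrics[["network", "n_edges", "n_movements",
                   "edge_density"]].to_string(index=False))
    print(f"outputs        : {OUT}")


if __name__ == "__main__":
    sys.exit(main())
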