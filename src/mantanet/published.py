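"""Published network-level metrics from the Raja Ampat reef manta study.

These are the values reported for the observed *Mobula alfredi* movement
network recorded by the 34-receiver Raja Ampat array (February 2016 to
September 2021). They are study *inputs* for worked examples and arithmetic
consistency checks — the package recomputes derived quantities (densities,
totals, per-individual means) from the printed counts; it does not assert
them from thin air.

Column order follows the published table: the archipelago-wide network first,
then the seven tagging-region networks.
"""

from __future__ import annotations

REGIONS = (
    "Raja Ampat",
    "Ayau",
    "Dampier Strait",
    "Fam and Bambu",
    "Kofiau and Boo",
    "Misool",
    "Wayag",
    "West Waigeo",
)

#: Reported network-level metrics. ``n_nodes_tagging_region`` is None for the
#: archipelago-wide column (not applicable).
NETWORK_METRICS = {
    "Raja Ampat":     dict(n_nodes=34, n_nodes_tagging_region=None, n_nodes_connected=32,
                           n_edges=131, n_movements=1094, edge_density=0.117, apl=2.71, diameter=6),
    "Ayau":           dict(n_nodes=34, n_nodes_tagging_region=3, n_nodes_connected=3,
                           n_edges=6, n_movements=46, edge_density=0.005, apl=1.0, diameter=1),
    "Dampier Strait": dict(n_nodes=34, n_nodes_tagging_region=10, n_nodes_connected=22,
                           n_edges=74, n_movements=288, edge_density=0.066, apl=2.73, diameter=6),
    "Fam and Bambu":  dict(n_nodes=34, n_nodes_tagging_region=5, n_nodes_connected=5,
                           n_edges=6, n_movements=7, edge_density=0.005, apl=1.83, diameter=4),
    "Kofiau and Boo": dict(n_nodes=34, n_nodes_tagging_region=1, n_nodes_connected=2,
                           n_edges=2, n_movements=2, edge_density=0.002, apl=1.0, diameter=1),
    "Misool":         dict(n_nodes=34, n_nodes_tagging_region=9, n_nodes_connected=10,
                           n_edges=43, n_movements=625, edge_density=0.038, apl=1.51, diameter=3),
    "Wayag":          dict(n_nodes=34, n_nodes_tagging_region=4, n_nodes_connected=2,
                           n_edges=1, n_movements=1, edge_density=0.001, apl=1.0, diameter=1),
    "West Waigeo":    dict(n_nodes=34, n_nodes_tagging_region=2, n_nodes_connected=9,
                           n_edges=20, n_movements=125, edge_density=0.018, apl=1.98, diameter=4),
}

#: Movements broken down by sex of the tagged animal.
SEX_MOVEMENTS = {"F": 777, "M": 315, "U": 2}

#: Tagging / detection summary counts.
N_TAGS_DEPLOYED = 117
N_TAGS_DETECTED = 94           # detected at least once
N_MULTI_STATION_ANIMALS = 72   # detected by two or more stations
REPORTED_MEAN_MOVEMENTS = 15   # mean movements per multi-station animal

#: Receivers per region as deployed (used by the simulator's default array).
STATIONS_PER_REGION = {
    "Ayau": 3,
    "Wayag": 4,
    "West Waigeo": 2,
    "Dampier Strait": 10,
    "Fam and Bambu": 5,
    "Kofiau and Boo": 1,
    "Misool": 9,
}

#: Transmitters deployed per tagging region.
TAGS_PER_REGION = {
    "Ayau": 6,
    "Wayag": 2,
    "West Waigeo": 28,
    "Dampier Strait": 36,
    "Fam and Bambu": 13,
    "Kofiau and Boo": 4,
    "Misool": 28,
}
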