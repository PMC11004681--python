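"""Residence-event extraction and between-station movements.

A *residence event* is a maximal run of detections of one transmitter at one
station: it opens at a detection, is extended by further detections at the
same station, and is terminated when the animal is detected at a different
station or goes undetected for longer than the timeout (60 min by default).
A *movement* is the transition between two consecutive residence events of
one transmitter at *distinct* stations; consecutive events at the same
station (a re-detection after a long silence) are not movements.

Boundary semantics, chosen here and configurable:

* a gap of exactly ``timeout_min`` continues the event (termination requires
  a strictly greater gap);
* detections with identical timestamps at two stations are ordered by
  station id for determinism and flagged with a data-quality warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geo import haversine_km

logger = logging.getLogger(__name__)

__all__ = [
    "extract_residence_events",
    "extract_movements",
    "movement_distances",
    "per_individual_summary",
]

EVENT_COLUMNS = ["transmitter_id", "station_id", "start", "end", "n_detections"]
MOVEMENT_COLUMNS = ["transmitter_id", "from_station", "to_station",
                    "depart", "arrive", "duration_min"]


def extract_residence_events(detections: pd.DataFrame,
                             timeout_min: float = 60.0,
                             min_detections: int = 1) -> pd.DataFrame:
    """Sweep each transmitter's detection stream into residence events.

    Parameters
    ----------
    detections : tidy detection table (``transmitter_id``, ``station_id``,
        ``timestamp``). If unsorted it is sorted internally (logged).
    timeout_min : silence longer than this closes the open event.
    min_detections : events with fewer detections are discarded (default 1,
        i.e. a single detection is a valid residence event).
    """
    if timeout_min <= 0:
        raise ValueError("timeout_min must be positive")
    if len(detections) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    d = detections
    sorted_ok = (d.groupby("transmitter_id", sort=False)["timestamp"]
                 .apply(lambda s: s.is_monotonic_increasing).all())
    if not sorted_ok:
        logger.info("detections not sorted per transmitter; sorting internally")
    # deterministic order; station_id breaks exact-timestamp ties
    d = d.sort_values(["transmitter_id", "timestamp", "station_id"],
                      kind="mergesort").reset_index(drop=True)
    dup = d.duplicated(subset=["transmitter_id", "timestamp"], keep=False)
    if dup.any():
        n_pairs = int(dup.sum())
        logger.warning(
            "%d detection(s) share an exact timestamp for one transmitter "
            "(possible overlapping detection ranges); ordered by station id",
            n_pairs)

    tid = d["transmitter_id"].to_numpy()
    st = d["station_id"].to_numpy()
    ts_ns = d["timestamp"].astype("int64").to_numpy()  # UTC ns since epoch
    timeout_ns = int(round(timeout_min * 60 * 1e9))
    same_tid = np.concatenate(([False], tid[1:] == tid[:-1]))
    same_st = np.concatenate(([False], st[1:] == st[:-1]))
    gap_ok = np.concatenate(([False], (ts_ns[1:] - ts_ns[:-1]) <= timeout_ns))
    extends = same_tid & same_st & gap_ok
    event_id = np.cumsum(~extends)

    g = d.assign(_eid=event_id).groupby("_eid", sort=True)
    events = g.agg(
        transmitter_id=("transmitter_id", "first"),
        station_id=("station_id", "first"),
        start=("timestamp", "first"),
        end=("timestamp", "last"),
        n_detections=("timestamp", "size"),
    ).reset_index(drop=True)
    if min_detections > 1:
        events = (events[events["n_detections"] >= min_detections]
                  .reset_index(drop=True))
    return events[EVENT_COLUMNS]


def extract_movements(events: pd.DataFrame) -> pd.DataFrame:
    """Derive movements from consecutive residence events at distinct stations.

    The departure time is the end of the earlier event, the arrival the start
    of the later one. Consecutive events at the same station produce nothing.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=MOVEMENT_COLUMNS)
    e = events.sort_values(["transmitter_id", "start"],
                           kind="mergesort").reset_index(drop=True)
    same_tid = e["transmitter_id"].shift() == e["transmitter_id"]
    diff_st = e["station_id"].shift() != e["station_id"]
    take = same_tid & diff_st
    moves = pd.DataFrame({
        "transmitter_id": e.loc[take, "transmitter_id"],
        "from_station": e["station_id"].shift()[take],
        "to_station": e.loc[take, "station_id"],
        "depart": e["end"].shift()[take],
        "arrive": e.loc[take, "start"],
    }).reset_index(drop=True)
    moves["duration_min"] = ((moves["arrive"] - moves["depart"])
                             / pd.Timedelta(minutes=1))
    if (moves["duration_min"] < 0).any():
        raise ValueError("overlapping residence events for one transmitter")
    return moves[MOVEMENT_COLUMNS].reset_index(drop=True)


def movement_distances(movements: pd.DataFrame,
                       stations: pd.DataFrame) -> pd.DataFrame:
    """Attach the great-circle (direct) distance in km to each movement."""
    out = movements.copy()
    if len(out) == 0:
        out["distance_km"] = pd.Series([], dtype=float)
        return out
    coords = stations.set_index("station_id")
    for col in ("from_station", "to_station"):
        unknown = set(out[col]) - set(coords.index)
        if unknown:
            raise KeyError(f"movement references unknown station(s): {sorted(unknown)}")
    out["distance_km"] = haversine_km(
        coords.loc[out["from_station"], "lat"].to_numpy(),
        coords.loc[out["from_station"], "lon"].to_numpy(),
        coords.loc[out["to_station"], "lat"].to_numpy(),
        coords.loc[out["to_station"], "lon"].to_numpy(),
    )
    return out


def per_individual_summary(movements: pd.DataFrame,
                           deployments: pd.DataFrame,
                           distance_stat: str = "mean") -> pd.DataFrame:
    """Per-animal movement summary for the animals that moved at all.

    Animals never detected at two or more stations produce no movements and
    are excluded, matching how multi-station animals form the analysis
    cohort. ``distance_stat`` selects whether the per-animal "direct
    distance travelled" is the mean (default) or the sum of its movements'
    great-circle legs.
    """
    if distance_stat not in ("mean", "sum"):
        raise ValueError("distance_stat must be 'mean' or 'sum'")
    meta = deployments.set_index("transmitter_id")
    if len(movements) == 0:
        return pd.DataFrame(columns=["animal_id", "transmitter_id", "sex",
                                     "tagging_region", "deploy_station",
                                     "n_movements", "distance_km"])
    g = movements.groupby("transmitter_id", sort=True)
    agg = g.agg(n_movements=("to_station", "size"))
    if "distance_km" in movements.columns:
        agg["distance_km"] = g["distance_km"].agg(distance_stat)
    else:
        agg["distance_km"] = np.nan
    agg = agg.reset_index()
    unknown = set(agg["transmitter_id"]) - set(meta.index)
    if unknown:
        raise KeyError(f"movements by undeployed transmitter(s): {sorted(unknown)}")
    for col in ("animal_id", "sex", "tagging_region", "deploy_station"):
        agg[col] = agg["transmitter_id"].map(meta[col])
    return agg[["animal_id", "transmitter_id", "sex", "tagging_region",
                "deploy_station", "n_movements", "distance_km"]]
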