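"""Reading detection logs and metadata, and the two false-positive filters.

A detection export (VUE-style) is a timestamped log of transmitter IDs heard
by receivers. Two filtering rules clean it before event extraction:

1. keep only transmitters that were actually deployed (drops false-positive
   decodes of codes never released), and
2. drop detections earlier than the transmitter's deployment time (pings
   logged while the tagger handled the transmitter).

Both filters are idempotent and only ever remove rows.
"""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionFormatError",
    "read_detections",
    "read_deployments",
    "read_stations",
    "filter_active",
    "filter_pre_tagging",
]

DETECTION_COLUMNS = ("datetime_utc", "receiver_id", "transmitter_id", "station_name")
DEPLOYMENT_COLUMNS = ("transmitter_id", "animal_id", "sex", "tagging_region",
                      "deploy_time", "deploy_station")
STATION_COLUMNS = ("station_id", "name", "region", "lat", "lon")


class DetectionFormatError(ValueError):
    """An input file is missing required structure."""


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DetectionFormatError(
            f"{what} is missing required column(s): {', '.join(missing)}")


def _to_utc(series: pd.Series, tz: str) -> pd.Series:
    ts = pd.to_datetime(series, errors="coerce", utc=False, format="mixed")
    if getattr(ts.dt, "tz", None) is None:
        ts = ts.dt.tz_localize(tz, ambiguous="NaT", nonexistent="NaT")
    return ts.dt.tz_convert("UTC")


def read_detections(path, stations: Optional[pd.DataFrame] = None,
                    tz: str = "UTC") -> pd.DataFrame:
    """Read a detection CSV into a tidy detection table.

    Parameters
    ----------
    path : file path of a CSV with columns ``datetime_utc``, ``receiver_id``,
        ``transmitter_id``, ``station_name`` (lines starting with ``#`` are
        provenance comments and ignored).
    stations : optional station table; when given, ``station_name`` is mapped
        to ``station_id`` (rows naming unknown stations raise).
    tz : timezone to assume for naive timestamps (receiver exports rarely
        carry offsets); everything is normalised to UTC.

    Returns a DataFrame with columns ``transmitter_id``, ``station_id``,
    ``timestamp`` sorted by (transmitter_id, timestamp). Rows whose timestamp
    cannot be parsed are dropped; the count is logged and recorded in
    ``df.attrs["n_malformed"]``.
    """
    raw = pd.read_csv(path, comment="#", dtype=str)
    _require_columns(raw, DETECTION_COLUMNS, "detection file")
    ts = _to_utc(raw["datetime_utc"], tz)
    bad = ts.isna()
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("dropped %d detection row(s) with unparseable timestamps", n_bad)
    out = pd.DataFrame({
        "transmitter_id": raw.loc[~bad, "transmitter_id"],
        "station_name": raw.loc[~bad, "station_name"],
        "timestamp": ts[~bad],
    })
    if stations is not None:
        name_to_id = stations.set_index("name")["station_id"]
        mapped = out["station_name"].map(name_to_id)
        if mapped.isna().any():
            unknown = sorted(out.loc[mapped.isna(), "station_name"].unique())
            raise DetectionFormatError(f"unknown station name(s): {unknown}")
        out["station_id"] = mapped
    else:
        out["station_id"] = out["station_name"]
    out = (out[["transmitter_id", "station_id", "timestamp"]]
           .sort_values(["transmitter_id", "timestamp"], kind="mergesort")
           .reset_index(drop=True))
    out.attrs["n_malformed"] = n_bad
    return out


def read_deployments(path, tz: str = "UTC") -> pd.DataFrame:
    """Read the tag-deployment metadata CSV (one row per transmitter)."""
    df = pd.read_csv(path, comment="#", dtype=str)
    _require_columns(df, DEPLOYMENT_COLUMNS, "deployment file")
    df = df.copy()
    df["deploy_time"] = _to_utc(df["deploy_time"], tz)
    if df["transmitter_id"].duplicated().any():
        dupes = sorted(df.loc[df["transmitter_id"].duplicated(), "transmitter_id"])
        raise DetectionFormatError(f"duplicate transmitter_id(s) in deployments: {dupes}")
    return df.reset_index(drop=True)


def read_stations(path) -> pd.DataFrame:
    """Read the station metadata CSV."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, STATION_COLUMNS, "station file")
    if df["station_id"].duplicated().any():
        raise DetectionFormatError("duplicate station_id in station table")
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        raise DetectionFormatError("coordinates outside valid lat/lon ranges")
    return df.reset_index(drop=True)


def filter_active(detections: pd.DataFrame,
                  deployments: pd.DataFrame) -> pd.DataFrame:
    """Keep only detections of transmitters that were actually deployed.

    Removes false-positive decodes: transmitter codes logged by a receiver
    that were never released in the study.
    """
    if len(deployments) == 0:
        raise ValueError("deployments table is empty")
    active = set(deployments["transmitter_id"])
    keep = detections["transmitter_id"].isin(active)
    out = detections.loc[keep].reset_index(drop=True)
    out.attrs["n_removed_inactive"] = int((~keep).sum())
    if out.attrs["n_removed_inactive"]:
        logger.info("removed %d detection(s) of undeployed transmitters",
                    out.attrs["n_removed_inactive"])
    return out


def filter_pre_tagging(detections: pd.DataFrame, deployments: pd.DataFrame,
                       buffer_min: float = 0.0) -> pd.DataFrame:
    """Drop detections recorded before a transmitter's deployment.

    Such rows come from the tagger handling a live transmitter near a
    receiver. A detection exactly at ``deploy_time`` is kept (closed lower
    bound). ``buffer_min`` additionally drops the first ``buffer_min``
    minutes after deployment (handling time); default 0.

    Every transmitter present in ``detections`` must have a ``deploy_time``.
    """
    deploy = deployments.set_index("transmitter_id")["deploy_time"]
    missing = set(detections["transmitter_id"]) - set(deploy.index)
    if missing:
        raise ValueError(
            f"transmitter(s) without a deployment time: {sorted(missing)}")
    if deploy.isna().any():
        bad = sorted(deploy.index[deploy.isna()])
        raise ValueError(f"deployment time missing/unparseable for: {bad}")
    cutoff = (detections["transmitter_id"].map(deploy)
              + pd.to_timedelta(buffer_min, unit="min"))
    keep = detections["timestamp"] >= cutoff
    out = detections.loc[keep].reset_index(drop=True)
    out.attrs["n_removed_pre_tagging"] = int((~keep).sum())
    if out.attrs["n_removed_pre_tagging"]:
        logger.info("removed %d pre-deployment detection(s)",
                    out.attrs["n_removed_pre_tagging"])
    return out
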