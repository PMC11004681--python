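import numpy as np
import pandas as pd
import pytest

from mantanet.simulate import SimConfig, simulate_study

UTC = "UTC"


def ts(minutes, base="2020-01-01T00:00:00Z"):
    """Timestamp `minutes` after an arbitrary base instant."""
    return pd.Timestamp(base) + pd.Timedelta(minutes=float(minutes))


def detections_frame(rows):
    """Build a tidy detection table from (transmitter, station, minutes) rows."""
    return pd.DataFrame(
        [dict(transmitter_id=t, station_id=s, timestamp=ts(m))
         for t, s, m in rows]
    ).sort_values(["transmitter_id", "timestamp"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def small_sim():
    """A compact three-region study with perfect detection.

    Perfect detection plus arrival-anchored pings means the downstream
    pipeline should recover the ground-truth movement list exactly.
    """
    cfg = SimConfig(
        region_names=("North", "Centre", "South"),
        region_coords=((0.4, 131.0), (-0.5, 130.5), (-2.0, 130.3)),
        stations_per_region=(4, 4, 4),
        n_animals_per_region=(10, 10, 10),
        within_region_move_prob=0.4,
        between_region_move_prob=0.005,
        mean_residency_min=30.0,
        mean_absence_min=120.0,
        detection_prob=1.0,
        study_days=6.0,
        seed=11,
    )
    stations, traj, truth, det = simulate_study(cfg)
    return cfg, stations, traj, truth, det


@pytest.fixture(scope="session")
def small_sim_tables(small_sim):
    """Tidy detections + deployments for the compact study."""
    cfg, stations, traj, truth, det = small_sim
    detections = det.rename(columns={"datetime_utc": "timestamp"})[
        ["transmitter_id", "station_id", "timestamp"]]
    return detections, traj.deployments, stations, truth
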