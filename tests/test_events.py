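import numpy as np
import pandas as pd
import pytest

from mantanet.events import (extract_movements, extract_residence_events,
                             movement_distances, per_individual_summary)
from mantanet.geo import haversine_km

from conftest import detections_frame, ts


# --------------------------------------------------------------------------
# independent brute-force oracle: a plain one-detection-at-a-time scanner
# --------------------------------------------------------------------------

def brute_force_events(det, timeout_min=60.0, min_detections=1):
    out = []
    for tid, grp in det.groupby("transmitter_id", sort=True):
        grp = grp.sort_values(["timestamp", "station_id"], kind="mergesort")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None:
                cur = [tid, row.station_id, row.timestamp, row.timestamp, 1]
            elif (row.station_id == cur[1]
                  and (row.timestamp - cur[3])
                  <= pd.Timedelta(minutes=timeout_min)):
                cur[3] = row.timestamp
                cur[4] += 1
            else:
                out.append(cur)
                cur = [tid, row.station_id, row.timestamp, row.timestamp, 1]
        if cur is not None:
            out.append(cur)
    df = pd.DataFrame(out, columns=["transmitter_id", "station_id",
                                    "start", "end", "n_detections"])
    return df[df["n_detections"] >= min_detections].reset_index(drop=True)


def brute_force_movements(events):
    rows = []
    for tid, grp in events.groupby("transmitter_id", sort=True):
        grp = grp.sort_values("start")
        prev = None
        for row in grp.itertuples(index=False):
            if prev is not None and row.station_id != prev.station_id:
                rows.append(dict(transmitter_id=tid,
                                 from_station=prev.station_id,
                                 to_station=row.station_id,
                                 depart=prev.end, arrive=row.start))
            prev = row
    return pd.DataFrame(rows, columns=["transmitter_id", "from_station",
                                       "to_station", "depart", "arrive"])


def random_streams(n_streams, rng, stations=("A", "B", "C", "D")):
    rows = []
    for k in range(n_streams):
        tid = f"T{k:04d}"
        t = 0.0
        for _ in range(int(rng.integers(1, 30))):
            # gaps straddle the 60-min timeout so both rules fire
            t += float(rng.exponential(40.0)) + 0.01
            rows.append((tid, str(rng.choice(stations)), t))
    return detections_frame(rows)


class TestResidenceEvents:
    def test_same_station_within_timeout_extends(self):
        det = detections_frame([("T", "A", 0), ("T", "A", 30), ("T", "B", 40)])
        ev = extract_residence_events(det)
        assert len(ev) == 2
        a, b = ev.iloc[0], ev.iloc[1]
        assert (a.station_id, a.n_detections) == ("A", 2)
        assert a.start == ts(0) and a.end == ts(30)
        assert (b.station_id, b.n_detections) == ("B", 1)
        assert b.start == b.end == ts(40)

    def test_single_detection_is_an_event(self):
        ev = extract_residence_events(detections_frame([("T", "A", 0)]))
        assert len(ev) == 1
        assert ev.loc[0, "start"] == ev.loc[0, "end"]
        assert ev.loc[0, "n_detections"] == 1

    def test_gap_exactly_at_timeout_continues(self):
        # termination requires a strictly greater gap
        det = detections_frame([("T", "A", 0), ("T", "A", 60)])
        assert len(extract_residence_events(det, timeout_min=60)) == 1
        det = detections_frame([("T", "A", 0), ("T", "A", 60.001)])
        assert len(extract_residence_events(det, timeout_min=60)) == 2

    def test_min_detections_discards_singletons(self):
        det = detections_frame([("T", "A", 0), ("T", "A", 10), ("T", "B", 20)])
        ev = extract_residence_events(det, min_detections=2)
        assert list(ev["station_id"]) == ["A"]

    def test_matches_brute_force_on_random_streams(self):
        rng = np.random.default_rng(7)
        det = random_streams(300, rng)
        fast = extract_residence_events(det)
        slow = brute_force_events(det)
        pd.testing.assert_frame_equal(fast, slow)

    def test_split_at_long_gap_equals_whole_stream(self):
        rng = np.random.default_rng(21)
        det = random_streams(50, rng, stations=("A", "B"))
        whole = extract_residence_events(det)
        # split each transmitter's stream at its first gap > timeout
        parts = []
        for tid, grp in det.groupby("transmitter_id"):
            gaps = grp["timestamp"].diff() > pd.Timedelta(minutes=60)
            if gaps.any():
                cut = gaps.idxmax()
                pos = grp.index.get_loc(cut)
                parts.extend([grp.iloc[:pos], grp.iloc[pos:]])
            else:
                parts.append(grp)
        halves = pd.concat([extract_residence_events(p.reset_index(drop=True))
                            for p in parts]).reset_index(drop=True)
        halves = halves.sort_values(["transmitter_id", "start"]) \
            .reset_index(drop=True)
        pd.testing.assert_frame_equal(whole, halves)


class TestMovements:
    def test_alternating_stations(self):
        det = detections_frame([("T", "A", 0), ("T", "B", 120), ("T", "A", 240)])
        mv = extract_movements(extract_residence_events(det))
        assert list(zip(mv["from_station"], mv["to_station"])) == [
            ("A", "B"), ("B", "A")]
        assert (mv["duration_min"] == 120.0).all()

    def test_same_station_after_long_gap_is_not_a_movement(self):
        det = detections_frame([("T", "A", 0), ("T", "A", 200)])
        ev = extract_residence_events(det)
        assert len(ev) == 2
        assert len(extract_movements(ev)) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        det = random_streams(200, rng)
        ev = extract_residence_events(det)
        fast = extract_movements(ev)
        slow = brute_force_movements(ev)
        pd.testing.assert_frame_equal(
            fast.drop(columns="duration_min"), slow)

    def test_recovers_simulated_ground_truth(self, small_sim_tables):
        detections, _, _, truth = small_sim_tables
        mv = extract_movements(extract_residence_events(detections))
        got = mv[["transmitter_id", "from_station", "to_station"]] \
            .reset_index(drop=True)
        want = (truth.true_movements
                .sort_values(["transmitter_id", "time"], kind="mergesort")
                [["transmitter_id", "from_station", "to_station"]]
                .reset_index(drop=True))
        pd.testing.assert_frame_equal(got, want)

    def test_movement_count_equals_adjacent_distinct_pairs(self, small_sim_tables):
        detections, *_ = small_sim_tables
        ev = extract_residence_events(detections)
        n_pairs = sum(
            (grp["station_id"].shift() != grp["station_id"]).iloc[1:].sum()
            for _, grp in ev.groupby("transmitter_id"))
        assert len(extract_movements(ev)) == n_pairs


class TestDistances:
    def test_zero_for_identical_coordinates(self):
        assert haversine_km(-1.0, 130.0, -1.0, 130.0) == 0.0

    def test_one_degree_meridian(self):
        # pi * 6371 / 180 = 111.1949 km
        assert haversine_km(0.0, 130.0, 1.0, 130.0) == pytest.approx(111.19, abs=0.01)

    def test_against_law_of_cosines_oracle(self):
        rng = np.random.default_rng(3)
        lat1, lat2 = rng.uniform(-60, 60, (2, 200))
        lon1, lon2 = rng.uniform(-180, 180, (2, 200))
        got = haversine_km(lat1, lon1, lat2, lon2)
        p1, p2 = np.radians(lat1), np.radians(lat2)
        dl = np.radians(lon2 - lon1)
        want = 6371.0 * np.arccos(np.clip(
            np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl),
            -1, 1))
        assert np.allclose(got, want, rtol=1e-3, atol=1e-6)

    def test_unknown_station_errors(self):
        stations = pd.DataFrame([dict(station_id="A", name="A", region="r",
                                      lat=0.0, lon=130.0)])
        mv = pd.DataFrame([dict(transmitter_id="T", from_station="A",
                                to_station="Z", depart=ts(0), arrive=ts(1),
                                duration_min=1.0)])
        with pytest.raises(KeyError, match="Z"):
            movement_distances(mv, stations)


class TestPerIndividualSummary:
    def _stations(self):
        return pd.DataFrame([
            dict(station_id="A", name="A", region="r", lat=0.0, lon=130.0),
            dict(station_id="B", name="B", region="r", lat=0.0, lon=130.2),
        ])

    def test_mean_distance_and_count(self):
        mv = pd.DataFrame([
            dict(transmitter_id="T1", from_station="A", to_station="B",
                 depart=ts(0), arrive=ts(1), duration_min=1.0, distance_km=10.0),
            dict(transmitter_id="T1", from_station="B", to_station="A",
                 depart=ts(2), arrive=ts(3), duration_min=1.0, distance_km=30.0),
        ])
        dep = pd.DataFrame([dict(transmitter_id="T1", animal_id="M1", sex="F",
                                 tagging_region="r", deploy_station="A",
                                 deploy_time=ts(-10))])
        tab = per_individual_summary(mv, dep)
        assert tab.loc[0, "n_movements"] == 2
        assert tab.loc[0, "distance_km"] == 20.0
        tab_sum = per_individual_summary(mv, dep, distance_stat="sum")
        assert tab_sum.loc[0, "distance_km"] == 40.0

    def test_non_moving_animals_excluded(self, small_sim_tables):
        detections, deployments, stations, _ = small_sim_tables
        mv = movement_distances(
            extract_movements(extract_residence_events(detections)), stations)
        tab = per_individual_summary(mv, deployments)
        assert set(tab["transmitter_id"]) == set(mv["transmitter_id"])
        # additivity: per-animal totals sum to the global movement count
        assert tab["n_movements"].sum() == len(mv)

    def test_totals_match_ground_truth(self, small_sim_tables):
        detections, deployments, _, truth = small_sim_tables
        mv = extract_movements(extract_residence_events(detections))
        tab = per_individual_summary(mv, deployments)
        want = truth.true_movements.groupby("transmitter_id").size()
        got = tab.set_index("transmitter_id")["n_movements"]
        pd.testing.assert_series_equal(got.sort_index(), want.sort_index(),
                                       check_names=False, check_dtype=False)
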