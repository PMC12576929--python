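import numpy as np
import pandas as pd
import pytest

from movekba.tracks_io import ColonySite, unproject_local
from movekba.trips import (
    Trip,
    filter_colonies,
    filter_complete,
    interpolate_track,
    split_trips,
    trip_metrics,
)

COLONY = ColonySite("c1", lon=0.0, lat=54.0)


def stream_from_distances(dist_km, interval_s=100.0):
    """Fix stream due east of the colony at the given distances."""
    dist_km = np.asarray(dist_km, dtype=float)
    lon, lat = unproject_local(dist_km, np.zeros_like(dist_km), COLONY)
    t0 = pd.Timestamp("2026-06-01T00:00:00Z")
    return pd.DataFrame(
        {
            "individual_id": "b1",
            "colony_id": "c1",
            "timestamp": [t0 + pd.Timedelta(seconds=interval_s * i) for i in range(len(dist_km))],
            "lon": lon,
            "lat": lat,
        }
    )


def block(dist_km, minutes, interval_s=100.0):
    n = int(round(minutes * 60 / interval_s))
    return [dist_km] * n


class TestSplitTrips:
    def test_two_complete_trips_hand_trace(self):
        # 20 min beyond 1 km; 15 min inside the return buffer; 30 min beyond;
        # ends with >= 14 min inside -> exactly 2 complete trips
        d = block(5.0, 20) + block(0.7, 15) + block(5.0, 30) + block(0.7, 15)
        trips = split_trips(stream_from_distances(d), COLONY, min_trip_fixes=1)
        assert len(trips) == 2
        assert all(t.complete for t in trips)

    def test_all_fixes_in_inner_buffer_no_trips(self):
        trips = split_trips(stream_from_distances(block(0.3, 60)), COLONY)
        assert trips == []

    def test_short_final_return_flags_incomplete(self):
        # excursion ends with only 5 min inside the return buffer
        d = block(5.0, 30) + block(0.7, 5)
        trips = split_trips(stream_from_distances(d), COLONY, min_trip_fixes=1)
        assert len(trips) == 1
        assert not trips[0].complete

    def test_no_trip_fix_within_inner_buffer(self):
        d = block(0.3, 20) + block(5.0, 30) + block(0.3, 20)
        trips = split_trips(stream_from_distances(d), COLONY, min_trip_fixes=1)
        assert len(trips) == 1
        assert (trips[0].fixes["dist_colony_km"] > 0.5).all()

    def test_invariant_to_padding_with_colony_fixes(self):
        d = block(5.0, 30) + block(0.2, 20)
        base = split_trips(stream_from_distances(d), COLONY, min_trip_fixes=1)
        padded = block(0.2, 30) + d + block(0.2, 30)
        pad = split_trips(stream_from_distances(padded), COLONY, min_trip_fixes=1)
        assert len(base) == len(pad) == 1
        assert base[0].n_fixes == pad[0].n_fixes

    def test_unordered_timestamps_rejected(self):
        df = stream_from_distances(block(5.0, 10))
        df = df.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            split_trips(df, COLONY)

    def test_empty_input_empty_output(self):
        assert split_trips(stream_from_distances([]), COLONY) == []

    def test_fix_conservation(self):
        d = block(5.0, 20) + block(0.7, 15) + block(8.0, 40) + block(0.7, 15)
        df = stream_from_distances(d)
        trips = split_trips(df, COLONY, min_trip_fixes=1)
        assert sum(t.n_fixes for t in trips) <= len(df)


class TestFilterComplete:
    def _trip(self, complete):
        return Trip("t", "b", "c", pd.DataFrame(), complete=complete)

    def test_keeps_only_complete_in_order(self):
        trips = [self._trip(True), self._trip(False), self._trip(True), self._trip(True)]
        assert [t.complete for t in filter_complete(trips)] == [True, True, True]

    def test_all_incomplete_gives_empty(self):
        assert filter_complete([self._trip(False)] * 3 ) == []

    def test_idempotent(self):
        trips = [self._trip(True), self._trip(False)]
        once = filter_complete(trips)
        assert filter_complete(once) == once


class TestTripMetrics:
    def test_collinear_outbound(self):
        fx = stream_from_distances([0.0, 5.0, 10.0])
        trip = Trip("t", "b1", "c1", fx, complete=True)
        m = trip_metrics(trip, COLONY)
        assert m["total_distance_km"] == pytest.approx(10.0, rel=1e-3)
        assert m["max_distance_km"] == pytest.approx(10.0, rel=1e-3)
        assert m["duration_h"] == pytest.approx(200 / 3600)

    def test_out_and_back(self):
        fx = stream_from_distances([0.0, 5.0, 0.0])
        m = trip_metrics(Trip("t", "b1", "c1", fx, complete=True), COLONY)
        assert m["total_distance_km"] == pytest.approx(10.0, rel=1e-3)
        assert m["max_distance_km"] == pytest.approx(5.0, rel=1e-3)

    def test_two_identical_fixes_degenerate(self):
        fx = stream_from_distances([3.0, 3.0])
        m = trip_metrics(Trip("t", "b1", "c1", fx, complete=True), COLONY)
        assert m["total_distance_km"] == 0.0
        assert m["max_distance_km"] == pytest.approx(3.0, rel=1e-3)

    def test_single_fix_rejected(self):
        fx = stream_from_distances([3.0])
        with pytest.raises(ValueError):
            trip_metrics(Trip("t", "b1", "c1", fx, complete=True), COLONY)


class TestFilterColonies:
    def _trips(self, colony, individuals, year=2026):
        out = []
        for i in individuals:
            fx = pd.DataFrame({"timestamp": [pd.Timestamp(f"{year}-06-01T00:00:00Z")]})
            out.append(Trip(f"{i}_t0", i, colony, fx, complete=True))
        return out

    def test_eight_individuals_one_year_retained(self):
        trips = self._trips("cA", [f"b{i}" for i in range(8)])
        retained, _ = filter_colonies(trips)
        assert retained == {"cA"}

    def test_seven_individuals_excluded(self):
        trips = self._trips("cA", [f"b{i}" for i in range(7)])
        retained, _ = filter_colonies(trips)
        assert retained == set()

    def test_year_with_too_few_individuals_excludes_colony(self):
        trips = self._trips("cA", [f"b{i}" for i in range(8)], year=2025)
        trips += self._trips("cA", ["b8", "b9"], year=2026)  # 2 < 3 in 2026
        retained, summary = filter_colonies(trips)
        assert retained == set()
        assert summary.loc[0, "n_individuals"] == 10


class TestInterpolation:
    def test_on_grid_identity(self):
        fx = pd.DataFrame(
            {
                "timestamp": pd.date_range("2026-06-01", periods=5, freq="100s", tz="UTC"),
                "x": np.arange(5.0),
                "y": np.zeros(5),
            }
        )
        out = interpolate_track(fx, 100.0)
        np.testing.assert_allclose(out["x"], fx["x"])
        np.testing.assert_allclose(out["y"], fx["y"])

    def test_midpoint_for_double_interval(self):
        fx = pd.DataFrame(
            {
                "timestamp": [pd.Timestamp("2026-06-01T00:00:00Z"),
                              pd.Timestamp("2026-06-01T00:03:20Z")],
                "x": [0.0, 2.0],
                "y": [0.0, 4.0],
            }
        )
        out = interpolate_track(fx, 100.0)
        assert len(out) == 3
        assert out.loc[1, "x"] == pytest.approx(1.0)
        assert out.loc[1, "y"] == pytest.approx(2.0)

    def test_long_gap_interpolates_interior_points(self):
        fx = pd.DataFrame(
            {
                "timestamp": [pd.Timestamp("2026-06-01T00:00:00Z"),
                              pd.Timestamp("2026-06-01T00:16:40Z")],  # 1000 s
                "x": [0.0, 10.0],
                "y": [0.0, 0.0],
            }
        )
        out = interpolate_track(fx, 100.0)
        interior = out.iloc[1:-1]
        assert len(interior) == 9
        assert (interior["x"] > 0).all() and (interior["x"] < 10).all()
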