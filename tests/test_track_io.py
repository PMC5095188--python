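"""Reader, burst partitioning, local projection and ground velocities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermalsoar.errors import ConfigurationError, SegmentationContractError
from thermalsoar.track_io import (
    R_EARTH,
    PlanarWindow,
    geodetic_to_planar,
    ground_velocity,
    planar_to_geodetic,
    project_window,
    read_track,
    read_tracks,
    split_bursts,
)


def _csv_frame(n=600, gap_at=None, density=True, start="2015-03-01T06:00:00"):
    times = pd.date_range(start, periods=n, freq="1s")
    if gap_at is not None:
        times = times.to_series().reset_index(drop=True)
        times.iloc[gap_at:] += pd.Timedelta(seconds=4)  # total step of 5 s
    df = pd.DataFrame(
        {
            "timestamp": times,
            "location-long": 90.4 + 1e-5 * np.arange(n),
            "location-lat": np.full(n, 27.5),
            "height-above-msl": np.full(n, 1500.0),
            "individual-local-identifier": "yoezer",
        }
    )
    if density:
        df["air-density"] = 1.05
    return df


class TestReader:
    def test_single_burst_roundtrip(self, tmp_path):
        path = tmp_path / "t.csv"
        _csv_frame(600).to_csv(path, index=False)
        track = read_track(path)
        assert len(track) == 600
        assert track.bursts == [(0, 600)]
        assert track.individual_id == "yoezer"
        assert np.all(np.isfinite(track.air_density))

    def test_gap_splits_bursts(self, tmp_path):
        path = tmp_path / "t.csv"
        _csv_frame(600, gap_at=300).to_csv(path, index=False)
        track = read_track(path)
        assert track.bursts == [(0, 300), (300, 600)]

    def test_missing_density_column_reads_as_nan(self, tmp_path):
        path = tmp_path / "t.csv"
        _csv_frame(60, density=False).to_csv(path, index=False)
        track = read_track(path)
        assert np.all(np.isnan(track.air_density))

    def test_bad_rows_dropped_and_missing_column_raises(self, tmp_path):
        df = _csv_frame(50)
        df["location-long"] = df["location-long"].astype(object)
        df.loc[10, "location-long"] = "not-a-number"
        df.loc[20, "location-lat"] = 123.0  # out of range
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        track = read_track(path)
        assert len(track) == 48

        df2 = df.drop(columns=["location-lat"])
        df2.to_csv(path, index=False)
        with pytest.raises(ConfigurationError):
            read_tracks(path)

    def test_duplicate_timestamps_keep_first(self, tmp_path):
        df = _csv_frame(40)
        df.loc[5, "timestamp"] = df.loc[4, "timestamp"]
        df.loc[5, "height-above-msl"] = 9999.0  # marker on the dropped row
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        track = read_track(path)
        assert len(track) == 39
        assert 9999.0 not in track.altitude

    def test_reader_preserves_time_order(self, tmp_path):
        df = _csv_frame(30).sample(frac=1.0, random_state=0)  # shuffled rows
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        track = read_track(path)
        assert np.all(np.diff(track.times).astype(int) == 1)


class TestBursts:
    def test_burst_partition_from_timestamps_only(self):
        times = np.array(
            ["2015-01-01T00:00:00", "2015-01-01T00:00:01", "2015-01-01T00:00:02",
             "2015-01-01T00:00:10", "2015-01-01T00:00:11"],
            dtype="datetime64[s]",
        )
        assert split_bursts(times) == [(0, 3), (3, 5)]


class TestProjection:
    def test_longitude_offset_oracle(self):
        # 0.001 deg east at lat 27: x = R cos(27 deg) * 0.001 * pi/180
        x, y = geodetic_to_planar(90.401, 27.0, 90.4, 27.0)
        expected = R_EARTH * np.cos(np.deg2rad(27.0)) * np.deg2rad(0.001)
        assert x == pytest.approx(expected, abs=1e-9)
        assert x == pytest.approx(99.08, abs=0.01)
        assert y == 0.0

    def test_identical_fixes_project_to_origin(self):
        times = np.datetime64("2015-01-01T00:00:00") + np.arange(31).astype(
            "timedelta64[s]")
        w = project_window(times, np.full(31, 90.4), np.full(31, 27.5),
                           np.full(31, 1000.0))
        assert np.allclose(w.x, 0.0) and np.allclose(w.y, 0.0)

    def test_window_contract_enforced(self):
        times = np.datetime64("2015-01-01T00:00:00") + np.arange(31).astype(
            "timedelta64[s]")
        bad = times.copy()
        bad[-1] += np.timedelta64(3, "s")  # 33-s span
        with pytest.raises(SegmentationContractError):
            project_window(bad, np.full(31, 90.4), np.full(31, 27.5),
                           np.full(31, 1000.0))
        with pytest.raises(SegmentationContractError):
            project_window(times[:30], np.full(30, 90.4), np.full(30, 27.5),
                           np.full(30, 1000.0))

    @settings(max_examples=50, deadline=None)
    @given(
        x=st.floats(-1900, 1900),
        y=st.floats(-1900, 1900),
        lat=st.floats(-60, 60),
    )
    def test_projection_roundtrip(self, x, y, lat):
        lon2, lat2 = planar_to_geodetic(x, y, 90.4, lat)
        x2, y2 = geodetic_to_planar(lon2, lat2, 90.4, lat)
        assert x2 == pytest.approx(x, abs=1e-6)
        assert y2 == pytest.approx(y, abs=1e-6)


class TestGroundVelocity:
    @staticmethod
    def _window(x, y):
        t = np.arange(31.0)
        return PlanarWindow(0.0, 0.0, x, y, np.full(31, 1000.0), t)

    def test_stationary_and_linear_motion(self):
        v = ground_velocity(self._window(np.zeros(31), np.zeros(31)))
        assert np.allclose(v, 0.0)
        t = np.arange(31.0)
        v = ground_velocity(self._window(3.0 * t, np.zeros(31)))
        assert np.allclose(v[:, 0], 3.0, atol=1e-12)  # exact incl. endpoints
        assert np.allclose(v[:, 1], 0.0, atol=1e-12)

    def test_circle_speed_attenuation(self):
        # r = 30 m, period 15 s: interior speeds are attenuated by the
        # central-difference factor sin(w dt)/(w dt) relative to 2 pi r / T
        r, period = 30.0, 15.0
        omega = 2.0 * np.pi / period
        t = np.arange(31.0)
        v = ground_velocity(
            self._window(r * np.cos(omega * t), r * np.sin(omega * t)))
        speeds = np.hypot(v[1:-1, 0], v[1:-1, 1])
        true_speed = r * omega
        assert np.allclose(speeds, true_speed * np.sin(omega) / omega, rtol=1e-12)
        assert np.all(np.abs(speeds - true_speed) / true_speed < 0.03)
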