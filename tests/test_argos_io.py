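import io
import logging

import numpy as np
import pandas as pd
import pytest

from argosqc import argos_io, simulate, ssm_core
from argosqc.errormodel import ellipse_to_cov


LS_CSV = """id,date,lon,lat,lc
a1,2020-06-01T00:00:00Z,140.0,-35.0,3
a1,2020-06-01T01:00:00Z,140.1,-35.0,B
a1,2020-06-01T02:00:00Z,140.2,-35.1,A
"""


def read_str(text, datatype, **kw):
    return argos_io.read_track_table(io.StringIO(text), datatype, **kw)


class TestReadTrackTable:
    def test_small_ls_table_preserves_classes(self):
        (track,) = read_str(LS_CSV, "LS")
        assert len(track) == 3
        assert list(track.lc) == ["3", "B", "A"]
        assert track.datatype == "LS"

    def test_column_synonyms_accepted(self):
        text = LS_CSV.replace("id,date,lon,lat,lc",
                              "Ptt,Timestamp,Longitude,Latitude,Location Class")
        (track,) = read_str(text, "LS")
        assert len(track) == 3

    def test_duplicate_timestamps_shifted_stably(self):
        text = ("id,date,lon,lat,lc\n"
                "a1,2020-06-01T00:00:00Z,140.0,-35.0,3\n"
                "a1,2020-06-01T00:00:00Z,140.5,-35.5,2\n"
                "a1,2020-06-01T01:00:00Z,141.0,-36.0,1\n")
        (track,) = read_str(text, "LS")
        assert (np.diff(track.times.asi8) > 0).all()
        assert track.time_shift_s[1] == 10.0
        assert list(track.lc) == ["3", "2", "1"]  # order stable
        assert (track.times[1] - track.times[0]).total_seconds() == 10.0

    def test_swapped_ellipse_axes_repaired_to_same_covariance(self, caplog):
        text = ("id,date,lon,lat,smaj,smin,eor\n"
                "k1,2020-06-01T00:00:00Z,140.0,-35.0,5000,1000,30\n"
                "k1,2020-06-01T01:00:00Z,140.1,-35.0,1000,5000,30\n")
        with caplog.at_level(logging.WARNING):
            (track,) = read_str(text, "KF")
        assert "swapped" in caplog.text
        assert track.smaj[1] == 5.0 and track.smin[1] == 1.0
        assert track.eor[1] == pytest.approx(120.0)
        # the repaired record describes the identical error ellipse
        cov_ok = ellipse_to_cov(track.smaj[0], track.smin[0], track.eor[0])
        cov_fix = ellipse_to_cov(track.smaj[1], track.smin[1], track.eor[1])
        raw = np.array([[np.nan, np.nan], [np.nan, np.nan]])
        c = np.radians(30.0)
        a, b = 1.0, 5.0  # as reported: "major" 1 km, "minor" 5 km
        raw[0, 0] = (a / np.sqrt(2))**2 * np.sin(c)**2 + (b / np.sqrt(2))**2 * np.cos(c)**2
        raw[1, 1] = (a / np.sqrt(2))**2 * np.cos(c)**2 + (b / np.sqrt(2))**2 * np.sin(c)**2
        raw[0, 1] = raw[1, 0] = (a**2 - b**2) / 2 * np.cos(c) * np.sin(c)
        assert np.allclose(cov_fix, raw)
        assert not np.allclose(cov_fix, cov_ok)

    def test_z_class_policies(self):
        text = LS_CSV.replace("a1,2020-06-01T02:00:00Z,140.2,-35.1,A",
                              "a1,2020-06-01T02:00:00Z,140.2,-35.1,Z")
        (relabelled,) = read_str(text, "LS", z_policy="relabel")
        assert list(relabelled.lc) == ["3", "B", "B"]
        (dropped,) = read_str(text, "LS", z_policy="drop")
        assert len(dropped) == 2

    def test_missing_mandatory_column_lists_candidates(self):
        with pytest.raises(ValueError, match="lat.*latitude"):
            read_str("id,date,lon,lc\na,2020-01-01,1,3\n", "LS")

    def test_ls_rows_with_ellipses_rejected(self):
        text = ("id,date,lon,lat,lc,smaj,smin,eor\n"
                "a1,2020-06-01T00:00:00Z,140.0,-35.0,3,5000,1000,30\n")
        with pytest.raises(ValueError, match="mixes"):
            read_str(text, "LS")

    def test_unparseable_rows_dropped_with_count(self, caplog):
        text = LS_CSV + "a1,not-a-date,140.3,-35.2,B\na1,2020-06-01T03:00:00Z,oops,-35.3,B\n"
        with caplog.at_level(logging.WARNING):
            (track,) = read_str(text, "LS")
        assert len(track) == 3
        assert "dropped 2" in caplog.text

    def test_naive_timestamps_assumed_utc(self, caplog):
        text = LS_CSV.replace("Z,", ",").replace("00Z", "00")
        with caplog.at_level(logging.WARNING):
            (track,) = read_str(text, "LS")
        assert "assuming UTC" in caplog.text
        assert str(track.times[0].tz) == "UTC"

    def test_simulator_round_trip_conserves_observations(self, tmp_path):
        cfg = simulate.SimConfig(seed=3, duration_days=3.0)
        _, argos, gps = simulate.simulate_double_tagged(cfg)
        p = tmp_path / "argos.csv"
        argos.to_frame().to_csv(p, index=False)
        (back,) = argos_io.read_track_table(p, "KF")
        assert len(back) == len(argos)
        assert np.allclose(back.lon, argos.lon, atol=1e-9)
        assert np.allclose(back.smaj, argos.smaj, atol=1e-9)
        gp = tmp_path / "gps.csv"
        gps.to_frame().to_csv(gp, index=False)
        (gback,) = argos_io.read_track_table(gp, "GPS")
        assert len(gback) == len(gps)


class TestWriteEstimates:
    def make_estimates(self, rng, n=4):
        ests = []
        for i in range(n):
            cov = np.diag(rng.uniform(0.01, 1.0, 4))
            ests.append(ssm_core.StateEstimate(
                t=pd.Timestamp("2020-06-01T00:00Z") + pd.Timedelta(hours=2 * i),
                x=float(rng.normal(15500, 10)), y=float(rng.normal(-4400, 10)),
                vx=float(rng.normal()), vy=float(rng.normal()), cov=cov))
        return ests

    def test_round_trip(self, tmp_path, rng):
        ests = self.make_estimates(rng)
        p = tmp_path / "est.csv"
        argos_io.write_estimates({"a1": ests}, p)
        df = argos_io.read_estimates(p)
        assert len(df) == 4
        assert np.allclose(df["x"], [e.x for e in ests], atol=1e-9)
        assert np.allclose(df["lat"], [e.lat for e in ests], atol=1e-9)
        assert df["date"].iloc[0] == ests[0].t
        assert (df["x_se"] >= 0).all() and (df["y_se"] >= 0).all()

    def test_empty_set_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        argos_io.write_estimates({}, p)
        df = pd.read_csv(p)
        assert len(df) == 0
        assert "conf_smaj" in df.columns
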