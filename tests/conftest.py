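import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from argosqc import geo
from argosqc.argos_io import Track

T0 = pd.Timestamp("2020-06-01T00:00:00Z")


def make_track(lon, lat, t_hours, datatype="KF", track_id="t1", **extra):
    """Build a Track directly from geographic fixes (ellipse fields in km)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x, y = geo.project(geo.unwrap_lon(lon), lat)
    times = pd.DatetimeIndex(
        [T0 + pd.Timedelta(seconds=round(h * 3600.0, 6)) for h in t_hours]
    )
    if datatype in ("KF", "KS") and "smaj" not in extra:
        n = len(lon)
        extra.update(smaj=np.full(n, 1.0), smin=np.full(n, 0.5), eor=np.full(n, 90.0))
    return Track(id=track_id, datatype=datatype, times=times,
                 lon=lon, lat=lat, x=np.atleast_1d(x), y=np.atleast_1d(y), **extra)


def make_plane_track(x_km, y_km, t_hours, datatype="KF", track_id="t1", **extra):
    """Build a Track from plane coordinates near the projection origin."""
    x = np.asarray(x_km, dtype=float)
    y = np.asarray(y_km, dtype=float)
    lon, lat = geo.unproject(x, y)
    times = pd.DatetimeIndex(
        [T0 + pd.Timedelta(seconds=round(h * 3600.0, 6)) for h in t_hours]
    )
    if datatype in ("KF", "KS") and "smaj" not in extra:
        n = len(x)
        extra.update(smaj=np.full(n, 1.0), smin=np.full(n, 0.5), eor=np.full(n, 90.0))
    return Track(id=track_id, datatype=datatype, times=times,
                 lon=np.atleast_1d(lon), lat=np.atleast_1d(lat),
                 x=x, y=y, **extra)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
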