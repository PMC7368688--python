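"""Validation of model-estimated locations against GPS truth.

GPS fixes from double-tagged animals serve as ground truth. Because GPS and
Argos times never coincide, two pairing schemes are supported:

* ``interp`` — linear interpolation of the GPS track (per coordinate, in the
  projected km plane) to the estimate times; estimate times outside the GPS
  span are dropped with a logged count, never extrapolated.
* ``match`` — the temporally closest GPS fix within a +/- window (default
  10 min); ties broken by smaller absolute time difference, then by the
  earlier GPS fix; a GPS fix may pair with several estimate times.

Accuracy is summarised per track as the root mean of squared geodesic
distances (RMSD, km). Two methods are compared via the difference of log
RMSDs (log-delta RMSD), which approximates their fractional accuracy
difference; with scheme A under test against baseline B, negative
log(RMSD_A) - log(RMSD_B) means A is the more accurate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geo, ssm_core
from .argos_io import Track

logger = logging.getLogger(__name__)


@dataclass
class ValidationResult:
    track_id: str
    method: str                  # "interp" or "match"
    n_pairs: int
    rmsd_km: float
    distances_km: np.ndarray
    label: Optional[str] = None
    converged: bool = True


def _hours_since(times: pd.DatetimeIndex, t0: pd.Timestamp) -> np.ndarray:
    return (times.asi8 - t0.value) / 3.6e12


def interp_gps(gps: Track, times: pd.DatetimeIndex):
    """Linearly interpolate the GPS track to the requested times.

    Returns ``(xy, kept)``: interpolated (k, 2) km positions and the boolean
    mask of requested times inside the GPS span. Needs >= 2 GPS fixes.
    """
    if len(gps) < 2:
        raise ValueError(f"GPS track {gps.id!r} has {len(gps)} fixes; need >= 2")
    tg = _hours_since(gps.times, gps.times[0])
    tq = _hours_since(times, gps.times[0])
    kept = (tq >= tg[0]) & (tq <= tg[-1])
    if (~kept).any():
        logger.info("interp_gps: dropped %d of %d times outside the GPS span",
                    int((~kept).sum()), len(tq))
    xy = np.column_stack([np.interp(tq[kept], tg, gps.x),
                          np.interp(tq[kept], tg, gps.y)])
    return xy, kept


def match_gps(gps: Track, times: pd.DatetimeIndex, window_min: float = 10.0):
    """Pair each requested time with the closest GPS fix within the window.

    Returns ``(est_idx, gps_idx)`` integer arrays for the paired subset.
    """
    if window_min <= 0:
        raise ValueError(f"window must be > 0 min, got {window_min}")
    tg = _hours_since(gps.times, gps.times[0])
    tq = _hours_since(times, gps.times[0])
    w = window_min / 60.0
    est_idx, gps_idx = [], []
    for i, t in enumerate(tq):
        j = int(np.searchsorted(tg, t))
        # candidates: fix at/after t and fix before t; earlier wins exact ties
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(tg):
                d = abs(tg[k] - t)
                if d <= w and (best is None or d < best[0] - 1e-15):
                    best = (d, k)
        if best is not None:
            est_idx.append(i)
            gps_idx.append(best[1])
    return np.array(est_idx, dtype=int), np.array(gps_idx, dtype=int)


def rmsd(distances_km: Sequence[float]) -> float:
    """Root mean of squared distances, km."""
    d = np.asarray(distances_km, dtype=float)
    if d.size == 0:
        raise ValueError("RMSD of zero pairs is undefined")
    return float(np.sqrt(np.mean(d**2)))


def log_delta_rmsd(rmsd_a: float, rmsd_b: float) -> float:
    """log(rmsd_a) - log(rmsd_b); negative means scheme a is more accurate."""
    if rmsd_a <= 0 or rmsd_b <= 0:
        raise ValueError(f"RMSDs must be > 0, got ({rmsd_a}, {rmsd_b})")
    return float(np.log(rmsd_a) - np.log(rmsd_b))


def _distances_lonlat(lon1, lat1, xy2) -> np.ndarray:
    lon2, lat2 = geo.unproject(xy2[:, 0], xy2[:, 1])
    return np.atleast_1d(geo.geodesic_km(lon1, lat1, geo.wrap_lon(np.atleast_1d(lon2)), lat2))


def validate_positions(track_id: str, times: pd.DatetimeIndex,
                       lon: np.ndarray, lat: np.ndarray, gps: Track,
                       method: str = "interp", window_min: float = 10.0,
                       label: Optional[str] = None) -> ValidationResult:
    """RMSD of arbitrary located times (e.g. fitted states) against GPS."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if method == "interp":
        xy_gps, kept = interp_gps(gps, times)
        d = _distances_lonlat(lon[kept], lat[kept], xy_gps)
    elif method == "match":
        ei, gi = match_gps(gps, times, window_min)
        if len(ei) == 0:
            raise ValueError(
                f"no GPS fixes within +/-{window_min} min of any estimate "
                f"for track {track_id!r}")
        xy_gps = np.column_stack([gps.x[gi], gps.y[gi]])
        d = _distances_lonlat(lon[ei], lat[ei], xy_gps)
    else:
        raise ValueError(f"unknown matching method {method!r}")
    return ValidationResult(track_id=track_id, method=method, n_pairs=len(d),
                            rmsd_km=rmsd(d), distances_km=d, label=label)


def validate_estimates(estimates: Sequence[ssm_core.StateEstimate], gps: Track,
                       track_id: str = "", method: str = "interp",
                       window_min: float = 10.0,
                       label: Optional[str] = None) -> ValidationResult:
    times = pd.DatetimeIndex([e.t for e in estimates])
    lon = np.array([e.lon for e in estimates])
    lat = np.array([e.lat for e in estimates])
    return validate_positions(track_id, times, lon, lat, gps,
                              method=method, window_min=window_min, label=label)


def compare_psi(track: Track, gps: Track, method: str = "interp",
                window_min: float = 10.0, min_obs: int = 10):
    """Fit with and without the semi-minor inflation psi; compare accuracy.

    Both fits share the track's pre-filter mask and all other settings.
    Returns ``(result_psi, result_nopsi, log_delta)`` where negative
    log_delta means the psi model produced more accurate locations.
    """
    if track.datatype not in ("KF", "KS"):
        raise ValueError("the psi comparison applies to error-ellipse (KF/KS) data")
    out = []
    for est_psi, label in ((True, "psi"), (False, "no-psi")):
        f = ssm_core.fit(track, estimate_psi=est_psi, min_obs=min_obs)
        r = validate_estimates(ssm_core.smooth(f), gps, track_id=track.id,
                               method=method, window_min=window_min, label=label)
        r.converged = f.converged
        out.append(r)
    ld = log_delta_rmsd(out[0].rmsd_km, out[1].rmsd_km)
    return out[0], out[1], ld


def compare_smoothed_vs_raw(track: Track, gps: Track, method: str = "interp",
                            window_min: float = 10.0, min_obs: int = 10,
                            estimate_psi: bool = True):
    """Pre-filtered raw fixes vs model-fitted locations, against GPS.

    Both arms use the identical pre-filter mask and the identical set of
    observation times, so pair counts match. Returns
    ``(result_raw, result_model, log_delta)``; negative log_delta means the
    state-space model improved on the raw (pre-filtered) locations.
    """
    sub = track.retained()
    raw = validate_positions(track.id, sub.times, sub.lon, sub.lat, gps,
                             method=method, window_min=window_min, label="raw")
    f = ssm_core.fit(track, estimate_psi=estimate_psi, min_obs=min_obs)
    model = validate_estimates(ssm_core.smooth(f), gps, track_id=track.id,
                               method=method, window_min=window_min, label="model")
    model.converged = f.converged
    ld = log_delta_rmsd(model.rmsd_km, raw.rmsd_km)
    return raw, model, ld
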