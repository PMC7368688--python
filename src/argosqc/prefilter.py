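"""Travel-rate pre-filter for extreme outlier fixes.

Before state-space fitting, fixes implying biologically impossible travel
rates are flagged and ignored. The filter is the iterative both-neighbours
scheme of the classic Argos speed filter: an interior fix is removable only
when the speeds implied to BOTH its currently retained neighbours exceed the
threshold (removing on a single fast leg would delete the good neighbour of
an outlier); the worst offender is removed first and speeds are recomputed
after each removal, until no removable fix remains. Endpoints are never
removed. Speeds use geodesic distances on the WGS84 ellipsoid (the filter
runs on geographic coordinates, before projection).

Default threshold 3 m/s suits pinnipeds and sea turtles; fast fliers such
as gannets need ~17 m/s. Flagged fixes are masked, not deleted, so removal
fractions remain reportable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import geo
from .argos_io import Track

logger = logging.getLogger(__name__)

SPECIES_VMAX = {"pinniped": 3.0, "turtle": 3.0, "gannet": 17.0}


@dataclass(frozen=True)
class FilterResult:
    """Outcome of speed filtering one track.

    keep: mask aligned to the track (True = retained).
    peak_speed: worst implied speed (m/s) each fix showed to a retained
    neighbour at the moment of its evaluation; NaN where undefined.
    vmax: threshold used, m/s.
    """

    keep: np.ndarray
    peak_speed: np.ndarray
    vmax: float

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())


def _leg_speeds_ms(track: Track, idx: np.ndarray) -> np.ndarray:
    """Speeds (m/s) along consecutive legs of the retained subsequence idx."""
    lon, lat = track.lon[idx], track.lat[idx]
    d_km = geo.geodesic_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dt_h = np.diff(track.t_hours[idx])
    return np.asarray(d_km) * 1000.0 / (dt_h * 3600.0)


def speed_filter(track: Track, vmax: float = 3.0) -> FilterResult:
    """Flag interior fixes whose implied speeds to both neighbours exceed vmax.

    Parameters
    ----------
    track : Track
        At least 3 observations; shorter tracks are returned unfiltered.
    vmax : float
        Maximum plausible sustained travel rate, m/s (> 0).

    The procedure is deterministic: ties in the worst offending speed are
    broken by the earlier index. Filtering an already-filtered track removes
    nothing further, and raising vmax never removes more fixes.
    """
    if vmax <= 0:
        raise ValueError(f"vmax must be > 0 m/s, got {vmax}")
    n = len(track)
    keep = np.ones(n, dtype=bool)
    peak = np.full(n, np.nan)
    if n < 3:
        logger.warning("track %s has %d fixes (<3); speed filter skipped",
                       track.id, n)
        return FilterResult(keep=keep, peak_speed=peak, vmax=float(vmax))

    while True:
        idx = np.flatnonzero(keep)
        if len(idx) < 3:
            break
        v = _leg_speeds_ms(track, idx)  # leg j joins idx[j] and idx[j+1]
        # interior retained fixes idx[1:-1]: in-leg v[:-1], out-leg v[1:]
        both = np.minimum(v[:-1], v[1:])
        worse = np.maximum(v[:-1], v[1:])
        peak[idx[1:-1]] = worse
        offending = both > vmax
        if not offending.any():
            break
        # worst first; argmax takes the earliest on ties
        j = int(np.argmax(np.where(offending, both, -np.inf)))
        keep[idx[1 + j]] = False

    return FilterResult(keep=keep, peak_speed=peak, vmax=float(vmax))


def apply_filter(track: Track, result: FilterResult) -> Track:
    """Return the track with the filter mask recorded (fixes flagged, kept)."""
    out = track.subset(np.ones(len(track), dtype=bool))
    out.keep = result.keep.copy()
    return out
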