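"""Reading, validation and canonicalization of Argos and GPS track tables.

Input is delimited text with a header; one row per location fix with an
animal id, a UTC timestamp, longitude/latitude in decimal degrees, and either
an Argos quality class (Least-Squares data) or error-ellipse metadata
(Kalman filter/smoother data: semi-major axis, semi-minor axis in metres and
orientation in degrees from north). GPS rows carry neither. Rows are
canonicalized into :class:`Track` objects: time-sorted, de-duplicated,
class-Z policy applied, defective ellipses repaired, longitudes unwrapped
across the antimeridian, and coordinates projected to km (EPSG:3395).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geo

logger = logging.getLogger(__name__)

DATATYPES = ("LS", "KF", "KS", "GPS")

# accepted column-name synonyms, lower-cased, stripped of [ ._-]
COLUMN_SYNONYMS = {
    "id": ["id", "animalid", "individualid", "ref", "deployid", "ptt", "tagid"],
    "date": ["date", "datetime", "time", "timestamp", "gmt", "utc"],
    "lon": ["lon", "longitude", "long", "x"],
    "lat": ["lat", "latitude", "y"],
    "lc": ["lc", "lq", "locationclass", "locationquality", "class", "quality"],
    "smaj": ["smaj", "errorsemimajoraxis", "semimajoraxis", "errsemimajoraxis", "semimajor"],
    "smin": ["smin", "errorsemiminoraxis", "semiminoraxis", "errsemiminoraxis", "semiminor"],
    "eor": ["eor", "errorellipseorientation", "ellipseorientation", "orientation"],
}

DUP_TIME_STEP_S = 10.0  # perturbation applied to later duplicate timestamps


@dataclass(frozen=True)
class ArgosObservation:
    """One raw location fix with its quality metadata."""

    id: str
    t: pd.Timestamp
    lon: float
    lat: float
    datatype: str
    lc: Optional[str] = None
    smaj_m: Optional[float] = None   # ellipse semi-major axis, metres
    smin_m: Optional[float] = None   # ellipse semi-minor axis, metres
    eor_deg: Optional[float] = None  # semi-major orientation, deg from north


@dataclass
class Track:
    """Time-ordered fixes for one animal, projected to the km plane.

    ``smaj``/``smin`` are in km (converted from the metres CLS provides).
    ``keep`` is the pre-filter mask (all True before filtering); filtered
    fixes are flagged, never deleted. ``time_shift_s`` records the duplicate
    timestamp perturbations for provenance.
    """

    id: str
    datatype: str
    times: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    x: np.ndarray
    y: np.ndarray
    lc: Optional[np.ndarray] = None
    smaj: Optional[np.ndarray] = None
    smin: Optional[np.ndarray] = None
    eor: Optional[np.ndarray] = None
    keep: np.ndarray = field(default=None)  # type: ignore[assignment]
    time_shift_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n = len(self.times)
        if self.keep is None:
            self.keep = np.ones(n, dtype=bool)
        if self.time_shift_s is None:
            self.time_shift_s = np.zeros(n)
        for name in ("lon", "lat", "x", "y", "keep", "time_shift_s"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch on track {self.id}")
        if n > 1 and not (np.diff(self.times.asi8) > 0).all():
            raise ValueError(f"timestamps not strictly increasing on track {self.id}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def t_hours(self) -> np.ndarray:
        """Observation times as fractional hours since the first fix."""
        ns = self.times.asi8
        return (ns - ns[0]) / 3.6e12

    def retained(self) -> "Track":
        """The track restricted to fixes that passed the pre-filter."""
        return self.subset(self.keep)

    def subset(self, mask: np.ndarray) -> "Track":
        mask = np.asarray(mask, dtype=bool)
        opt = {
            name: (getattr(self, name)[mask] if getattr(self, name) is not None else None)
            for name in ("lc", "smaj", "smin", "eor")
        }
        return Track(
            id=self.id,
            datatype=self.datatype,
            times=self.times[mask],
            lon=self.lon[mask],
            lat=self.lat[mask],
            x=self.x[mask],
            y=self.y[mask],
            keep=self.keep[mask].copy(),
            time_shift_s=self.time_shift_s[mask],
            **opt,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.id,
                "date": self.times,
                "lon": self.lon,
                "lat": self.lat,
                "x": self.x,
                "y": self.y,
                "keep": self.keep,
                "time_shift_s": self.time_shift_s,
            }
        )
        if self.lc is not None:
            df["lc"] = self.lc
        if self.smaj is not None:
            df["smaj"] = self.smaj * 1000.0  # back to metres on output
            df["smin"] = self.smin * 1000.0
            df["eor"] = self.eor
        df["datatype"] = self.datatype
        return df


def _norm(name: str) -> str:
    return "".join(ch for ch in name.strip().lower() if ch not in " ._-")


def _map_columns(columns: Sequence[str], column_map: Optional[dict]) -> dict:
    """Resolve canonical -> actual column names, from an explicit map or synonyms."""
    resolved = {}
    if column_map:
        for canon, actual in column_map.items():
            if actual not in columns:
                raise KeyError(f"mapped column {actual!r} for {canon!r} not in file")
            resolved[canon] = actual
    by_norm = {_norm(c): c for c in columns}
    for canon, synonyms in COLUMN_SYNONYMS.items():
        if canon in resolved:
            continue
        for syn in synonyms:
            if syn in by_norm:
                resolved[canon] = by_norm[syn]
                break
    missing = [c for c in ("id", "date", "lon", "lat") if c not in resolved]
    if missing:
        raise ValueError(
            f"missing mandatory column(s) {missing}; accepted names: "
            + "; ".join(f"{c}: {COLUMN_SYNONYMS[c]}" for c in missing)
        )
    return resolved


def _dedup_times(times: pd.Series) -> tuple[pd.Series, np.ndarray]:
    """Perturb later duplicate timestamps by +10 s until unique, order stable."""
    t = times.to_numpy(dtype="datetime64[ns]").astype("int64").astype(float) / 1e9
    shift = np.zeros(len(t))
    step = DUP_TIME_STEP_S
    # repeat because a shifted time may collide with the next timestamp
    for _ in range(len(t)):
        dup = np.zeros(len(t), dtype=bool)
        seen = set()
        for i, ti in enumerate(t):
            if ti in seen:
                dup[i] = True
            seen.add(ti)
        if not dup.any():
            break
        t[dup] += step
        shift[dup] += step
        order = np.argsort(t, kind="stable")
        t, shift = t[order], shift[order]
    out = pd.Series(pd.to_datetime((t * 1e9).astype("int64"), utc=True))
    return out, shift


def build_track(df: pd.DataFrame, track_id: str, datatype: str,
                z_policy: str = "relabel") -> Track:
    """Canonicalize one animal's rows (already column-normalized) into a Track."""
    if datatype not in DATATYPES:
        raise ValueError(f"unknown datatype {datatype!r}; expected one of {DATATYPES}")
    df = df.copy()

    has_lc = "lc" in df and df["lc"].notna().any()
    has_ell = all(c in df for c in ("smaj", "smin", "eor")) and df[["smaj", "smin", "eor"]].notna().any().any()
    if datatype == "LS":
        if not has_lc:
            raise ValueError(f"LS track {track_id!r} has no location-class column")
        if has_ell:
            raise ValueError(f"track {track_id!r} mixes LS classes and error ellipses")
    elif datatype in ("KF", "KS"):
        if not has_ell:
            raise ValueError(f"{datatype} track {track_id!r} lacks ellipse columns")
        bad = df[["smaj", "smin", "eor"]].isna().any(axis=1)
        if bad.any():
            logger.warning("track %s: dropped %d rows with incomplete ellipses",
                           track_id, int(bad.sum()))
            df = df[~bad]

    if datatype == "LS":
        df["lc"] = df["lc"].astype(str).str.strip().str.upper()
        if z_policy == "relabel":
            df.loc[df["lc"] == "Z", "lc"] = "B"
        elif z_policy == "drop":
            df = df[df["lc"] != "Z"]
        else:
            raise ValueError(f"unknown class-Z policy {z_policy!r}")

    df = df.sort_values("date", kind="stable").reset_index(drop=True)
    times, shift = _dedup_times(df["date"])
    if (shift > 0).any():
        order = np.argsort(times.to_numpy(), kind="stable")
        df = df.iloc[np.argsort(df["date"].to_numpy(), kind="stable")].reset_index(drop=True)
        logger.warning("track %s: perturbed %d duplicate timestamps by +%gs steps",
                       track_id, int((shift > 0).sum()), DUP_TIME_STEP_S)

    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)

    smaj = smin = eor = None
    if datatype in ("KF", "KS"):
        smaj = df["smaj"].to_numpy(dtype=float) / 1000.0  # m -> km
        smin = df["smin"].to_numpy(dtype=float) / 1000.0
        eor = np.mod(df["eor"].to_numpy(dtype=float), 180.0)
        swapped = smin > smaj
        if swapped.any():
            logger.warning("track %s: %d ellipses had m > M; axes swapped, "
                           "orientation rotated 90 deg", track_id, int(swapped.sum()))
            smaj2 = np.where(swapped, smin, smaj)
            smin2 = np.where(swapped, smaj, smin)
            eor = np.where(swapped, np.mod(eor + 90.0, 180.0), eor)
            smaj, smin = smaj2, smin2
        nonpos = smin <= 0
        if nonpos.any():
            raise ValueError(
                f"track {track_id!r}: {int(nonpos.sum())} ellipse(s) with "
                "non-positive semi-minor axis"
            )

    lon_unwrapped = geo.unwrap_lon(lon)
    x, y = geo.project(lon_unwrapped, lat)
    x = np.atleast_1d(x)
    y = np.atleast_1d(y)

    return Track(
        id=str(track_id),
        datatype=datatype,
        times=pd.DatetimeIndex(times),
        lon=lon,
        lat=lat,
        x=x,
        y=y,
        lc=df["lc"].to_numpy(dtype=object) if datatype == "LS" else None,
        smaj=smaj,
        smin=smin,
        eor=eor,
        time_shift_s=shift,
    )


def read_track_table(path, datatype: str, column_map: Optional[dict] = None,
                     delimiter: str = ",", z_policy: str = "relabel") -> list[Track]:
    """Read a delimited track table into one Track per animal id.

    Rows with unparseable coordinates or timestamps are dropped with a logged
    count; timestamps without a timezone are assumed UTC (warned). Duplicate
    timestamps within an id are perturbed forward by 10-s steps, preserving
    order among distinct times.
    """
    raw = pd.read_csv(path, sep=delimiter)
    cols = _map_columns(list(raw.columns), column_map)
    df = pd.DataFrame({canon: raw[actual] for canon, actual in cols.items()})

    naive = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    if naive.notna().any() and getattr(naive.dt, "tz", None) is None:
        logger.warning("%s: timestamps lack a timezone; assuming UTC", path)
        df["date"] = naive.dt.tz_localize("UTC")
    else:
        df["date"] = pd.to_datetime(df["date"], errors="coerce", utc=True, format="mixed")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    bad = df[["date", "lon", "lat"]].isna().any(axis=1)
    if bad.any():
        logger.warning("%s: dropped %d unparseable rows", path, int(bad.sum()))
        df = df[~bad]

    tracks = []
    for track_id, group in df.groupby("id", sort=True):
        tracks.append(build_track(group, str(track_id), datatype, z_policy=z_policy))
    return tracks


def write_estimates(track_estimates, path) -> None:
    """Write fitted/predicted state estimates to CSV.

    ``track_estimates``: mapping of track id to a sequence of state estimates
    (objects with t, lon, lat, x, y, x_se, y_se, vx, vy, and 95% confidence
    ellipse attributes ell_major, ell_minor, ell_orient), or a DataFrame
    already in the output layout. Columns (stable): id, date, lon, lat, x, y,
    x_se, y_se, vx, vy, conf_smaj, conf_smin, conf_eor.
    """
    if isinstance(track_estimates, pd.DataFrame):
        df = track_estimates
    else:
        rows = []
        for track_id, ests in track_estimates.items():
            for e in ests:
                rows.append(
                    {
                        "id": track_id,
                        "date": e.t,
                        "lon": e.lon,
                        "lat": e.lat,
                        "x": e.x,
                        "y": e.y,
                        "x_se": e.x_se,
                        "y_se": e.y_se,
                        "vx": e.vx,
                        "vy": e.vy,
                        "conf_smaj": e.ell_major,
                        "conf_smin": e.ell_minor,
                        "conf_eor": e.ell_orient,
                    }
                )
        columns = ["id", "date", "lon", "lat", "x", "y", "x_se", "y_se",
                   "vx", "vy", "conf_smaj", "conf_smin", "conf_eor"]
        df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, float_format="%.12g")


def read_estimates(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_estimates`."""
    df = pd.read_csv(path)
    if len(df):
        df["date"] = pd.to_datetime(df["date"], utc=True, format="mixed")
    return df
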