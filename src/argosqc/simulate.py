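"""Synthetic double-tagged animals: true tracks plus Argos and GPS fixes.

The generator emulates the data regime the model targets so the whole
pipeline is testable without field data:

* a latent track simulated exactly from the velocity random walk (velocity
  increments with variance 2*D*Delta per axis, position integrating the new
  velocity) on the union of all sampling times — no discretization error;
* irregular Argos sampling (exponential gaps by default), observed either as
  Kalman-filter/smoother-style fixes with anisotropic error ellipses
  (lognormal semi-major axes, Beta-distributed shape ratios, orientations
  concentrated east-west, i.e. semi-minor axes roughly north-south, as the
  polar satellite orbits produce) or as Least-Squares-style fixes with a
  quality-class mixture and per-class error SDs;
* systematic ellipse bias: the REPORTED semi-minor axis is the true one
  divided by ``m_shrink`` while the error is drawn with the true axis, so a
  fitted inflation psi should recover m_shrink;
* occasional gross outliers whose reported ellipse is left unchanged
  (vastly underestimating their true error);
* contemporaneous higher-rate GPS fixes with small isotropic noise.

All randomness flows from the single seed; replicate i of an experiment
uses seed + i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import geo
from .argos_io import Track
from .errormodel import LsErrorTable, ellipse_to_cov

_T0 = pd.Timestamp("2020-01-01T00:00:00Z")


@dataclass
class SimConfig:
    """Study conditions for one synthetic double-tagged animal."""

    seed: int = 0
    duration_days: float = 10.0
    argos_gap_min: float = 30.0        # mean Argos inter-fix gap, minutes
    gap_dist: str = "exponential"      # or "regular"
    gps_gap_min: float = 15.0          # regular GPS inter-fix gap, minutes
    D: float = 0.05                    # velocity diffusion, km^2 h^-3
    start_lon: float = 140.0
    start_lat: float = -35.0
    datatype: str = "KF"               # Argos flavour to emit: LS, KF or KS
    # ellipse generation (KF/KS)
    ellipse_median_smaj_km: float = 5.0
    ellipse_log_sd: float = 0.6
    shape_beta: tuple = (2.0, 8.0)     # m/M ~ Beta; mean 0.2, Table-2-like
    orient_sd_deg: float = 25.0        # concentration of c around 90 (east-west)
    m_shrink: float = 1.0              # reported semi-minor = true / m_shrink
    # LS generation
    ls_mixture: dict = field(default_factory=lambda: {
        "3": 0.05, "2": 0.07, "1": 0.08, "0": 0.10, "A": 0.25, "B": 0.45})
    ls_tau_x: float = 0.30             # class-3 SD east, km
    ls_tau_y: float = 0.25             # class-3 SD north, km
    # outliers
    outlier_rate: float = 0.01
    outlier_km: float = 100.0
    # GPS
    gps_noise_km: float = 0.03

    def __post_init__(self):
        if self.datatype not in ("LS", "KF", "KS"):
            raise ValueError(f"datatype must be LS, KF or KS, not {self.datatype!r}")
        for nm in ("duration_days", "argos_gap_min", "gps_gap_min",
                   "ellipse_median_smaj_km", "ls_tau_x", "ls_tau_y",
                   "gps_noise_km", "m_shrink"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be nonnegative")
        tot = sum(self.ls_mixture.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"LS class mixture sums to {tot}, not 1")


@dataclass
class TruthTrack:
    """Latent states on the union of all sampling times."""

    t0: pd.Timestamp
    t_hours: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    argos_mask: np.ndarray
    gps_mask: np.ndarray


def _sample_times(config: SimConfig, rng: np.random.Generator):
    dur_h = config.duration_days * 24.0
    gap_h = config.argos_gap_min / 60.0
    if config.gap_dist == "regular":
        t_argos = np.arange(0.0, dur_h + 1e-9, gap_h)
    elif config.gap_dist == "exponential":
        gaps = rng.exponential(gap_h, size=int(np.ceil(dur_h / gap_h * 3)) + 10)
        gaps = np.maximum(gaps, 1.0 / 60.0)  # >= 1 min between transmissions
        t_argos = np.concatenate([[0.0], np.cumsum(gaps)])
        t_argos = t_argos[t_argos <= dur_h]
    else:
        raise ValueError(f"unknown gap distribution {config.gap_dist!r}")
    # GPS grid offset by half a gap so Argos and GPS times interleave
    g = config.gps_gap_min / 60.0
    t_gps = np.arange(g / 2.0, dur_h, g)
    return t_argos, t_gps


def simulate_truth(config: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> TruthTrack:
    """Exact simulation of the latent velocity random walk.

    With D = 0 the track is a straight constant-velocity line. Velocity
    increments over each interval Delta are N(0, 2*D*Delta) per axis; the
    position step uses the post-increment velocity.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t_argos, t_gps = _sample_times(config, rng)
    t = np.union1d(np.round(t_argos, 10), np.round(t_gps, 10))
    argos_mask = np.isin(t, np.round(t_argos, 10))
    gps_mask = np.isin(t, np.round(t_gps, 10))

    n = len(t)
    x0, y0 = geo.project(config.start_lon, config.start_lat)
    x = np.empty(n)
    y = np.empty(n)
    vx = np.empty(n)
    vy = np.empty(n)
    x[0], y[0] = x0, y0
    vx[0] = vy[0] = 0.0
    deltas = np.diff(t)
    eta = rng.normal(size=(n - 1, 2)) * np.sqrt(2.0 * config.D * deltas)[:, None]
    for i in range(1, n):
        vx[i] = vx[i - 1] + eta[i - 1, 0]
        vy[i] = vy[i - 1] + eta[i - 1, 1]
        x[i] = x[i - 1] + vx[i] * deltas[i - 1]
        y[i] = y[i - 1] + vy[i] * deltas[i - 1]
    return TruthTrack(t0=_T0, t_hours=t, x=x, y=y, vx=vx, vy=vy,
                      argos_mask=argos_mask, gps_mask=gps_mask)


def _times_to_index(t0: pd.Timestamp, t_hours: np.ndarray) -> pd.DatetimeIndex:
    return pd.DatetimeIndex([t0 + pd.Timedelta(seconds=round(h * 3600.0, 6))
                             for h in t_hours])


def _track_from_plane(track_id: str, datatype: str, t0, t_hours, xy, **extra) -> Track:
    lon_u, lat = geo.unproject(xy[:, 0], xy[:, 1])
    lon = geo.wrap_lon(np.atleast_1d(lon_u))
    return Track(
        id=track_id, datatype=datatype, times=_times_to_index(t0, t_hours),
        lon=np.atleast_1d(lon), lat=np.atleast_1d(lat),
        x=xy[:, 0].copy(), y=xy[:, 1].copy(), **extra,
    )


def observe_argos(truth: TruthTrack, config: SimConfig,
                  rng: Optional[np.random.Generator] = None,
                  track_id: str = "sim") -> Track:
    """Argos-like observations of the truth at the Argos sampling times.

    Returns a Track carrying either reported error ellipses (KF/KS, km
    internally) or quality classes (LS), plus gross outliers at the
    configured rate whose reported metadata is unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1_000_003)
    idx = np.flatnonzero(truth.argos_mask)
    t = truth.t_hours[idx]
    n = len(idx)
    xy_true = np.column_stack([truth.x[idx], truth.y[idx]])

    extra = {}
    if config.datatype in ("KF", "KS"):
        M = config.ellipse_median_smaj_km * np.exp(
            rng.normal(0.0, config.ellipse_log_sd, size=n))
        shape = rng.beta(*config.shape_beta, size=n)
        m_true = np.maximum(shape * M, 1e-4)
        c = np.mod(90.0 + rng.normal(0.0, config.orient_sd_deg, size=n), 180.0)
        cov = ellipse_to_cov(M, m_true, c, psi=1.0)
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
        err = np.einsum("nij,nj->ni", L, rng.normal(size=(n, 2)))
        m_rep = m_true / config.m_shrink
        extra = {"smaj": M, "smin": np.minimum(m_rep, M), "eor": c}
    else:
        classes = np.array(list(config.ls_mixture.keys()), dtype=object)
        probs = np.array([config.ls_mixture[str(c)] for c in classes])
        table = LsErrorTable.from_yaml()
        lc = rng.choice(classes, size=n, p=probs)
        sx = config.ls_tau_x * np.array([table.k_x[str(c)] for c in lc])
        sy = config.ls_tau_y * np.array([table.k_y[str(c)] for c in lc])
        err = np.column_stack([rng.normal(0.0, 1.0, n) * sx,
                               rng.normal(0.0, 1.0, n) * sy])
        extra = {"lc": lc}

    xy = xy_true + err
    is_outlier = rng.random(n) < config.outlier_rate
    if is_outlier.any():
        theta = rng.uniform(0.0, 2.0 * np.pi, size=int(is_outlier.sum()))
        disp = config.outlier_km * np.column_stack([np.cos(theta), np.sin(theta)])
        xy[is_outlier] += disp

    track = _track_from_plane(track_id, config.datatype, truth.t0, t, xy, **extra)
    track.planted_outlier = is_outlier  # generator-side truth, for tests
    return track


def observe_gps(truth: TruthTrack, config: SimConfig,
                rng: Optional[np.random.Generator] = None,
                track_id: str = "sim") -> Track:
    """GPS observations: truth at the GPS times plus small isotropic noise."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2_000_003)
    idx = np.flatnonzero(truth.gps_mask)
    t = truth.t_hours[idx]
    xy = np.column_stack([truth.x[idx], truth.y[idx]])
    xy = xy + rng.normal(0.0, config.gps_noise_km, size=xy.shape)
    return _track_from_plane(track_id, "GPS", truth.t0, t, xy)


def simulate_double_tagged(config: SimConfig, track_id: str = "sim"):
    """Truth plus paired Argos and GPS tracks from one seed."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_truth(config, rng)
    argos = observe_argos(truth, config, rng, track_id=track_id)
    gps = observe_gps(truth, config, rng, track_id=track_id)
    return truth, argos, gps
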