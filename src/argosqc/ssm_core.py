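"""Continuous-time random-walk state-space model for Argos tracks.

Movement model
--------------
Velocity performs a continuous-time Gaussian random walk: over an elapsed
time Delta (hours) each velocity component gains a zero-mean Gaussian
increment with variance 2*D*Delta, where D (km^2 h^-3) is the single
diffusion coefficient. Position integrates velocity exactly as

    x_i = x_{i-1} + v_i * Delta_i

i.e. the displacement uses the NEW velocity, which induces correlated
position/velocity process noise: per axis,

    Q = 2 D Delta * [[Delta^2, Delta], [Delta, 1]].

Observed locations are the true locations plus zero-mean Gaussian error with
per-fix covariance Omega_i built by :mod:`argosqc.errormodel` from either the
Argos quality class (Least-Squares data; base scales tau_x, tau_y and
correlation rho are model parameters) or the reported error ellipse
(Kalman filter/smoother data; the semi-minor inflation psi is a model
parameter).

Estimation
----------
The model is linear-Gaussian, so the likelihood is computed exactly by the
prediction-error decomposition of a Kalman filter over the irregular time
grid, maximised by quasi-Newton search over unconstrained transforms
(log D, log tau, atanh rho, log psi). State estimates ("fitted" locations at
the observation times, "predicted" locations on a regular grid) come from
the fixed-interval RTS smoother, which conditions every state on the whole
track. Parameter standard errors use the delta method on the numerical
Hessian of the negative log-likelihood in transformed space.

Units: km, hours, km/h throughout. The state vector is [x, y, vx, vy].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2
from statsmodels.tools.numdiff import approx_hess

from . import geo
from .argos_io import Track
from .errormodel import LsErrorTable, ellipse_to_cov, ls_cov

logger = logging.getLogger(__name__)

# diffuse-but-proper prior scales (km^2, (km/h)^2), centred on the first fix
KAPPA_POS = 1.0e6
KAPPA_VEL = 1.0e4

_LOG2PI = np.log(2.0 * np.pi)
_CHI2_95_2D = chi2.ppf(0.95, df=2)


@dataclass
class ModelParams:
    """Process and measurement parameters.

    D : velocity diffusion coefficient, km^2 h^-3 (> 0).
    tau_x, tau_y : class-3 measurement SDs, km (Least-Squares fits only).
    rho : east/north error correlation in (-1, 1) (Least-Squares only).
    psi : semi-minor-axis inflation, dimensionless > 0 (ellipse fits only).
    """

    D: float
    tau_x: Optional[float] = None
    tau_y: Optional[float] = None
    rho: Optional[float] = None
    psi: Optional[float] = None


@dataclass
class StateEstimate:
    """Posterior location/velocity at one time, with derived quantities."""

    t: pd.Timestamp
    x: float
    y: float
    vx: float
    vy: float
    cov: np.ndarray  # 4x4 over [x, y, vx, vy]
    lon: float = field(init=False)
    lat: float = field(init=False)

    def __post_init__(self):
        lon, lat = geo.unproject(self.x, self.y)
        self.lon = float(geo.wrap_lon(lon))
        self.lat = float(lat)

    @property
    def x_se(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def y_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    @property
    def _pos_eig(self):
        vals, vecs = np.linalg.eigh(self.cov[:2, :2])
        return vals, vecs

    @property
    def ell_major(self) -> float:
        """95% confidence ellipse semi-major axis, km."""
        vals, _ = self._pos_eig
        return float(np.sqrt(max(vals[-1], 0.0) * _CHI2_95_2D))

    @property
    def ell_minor(self) -> float:
        vals, _ = self._pos_eig
        return float(np.sqrt(max(vals[0], 0.0) * _CHI2_95_2D))

    @property
    def ell_orient(self) -> float:
        """Orientation of the 95% ellipse semi-major axis, deg cw from north."""
        vals, vecs = self._pos_eig
        ex, ey = vecs[:, -1]  # (east, north) components of the major axis
        return float(np.mod(np.degrees(np.arctan2(ex, ey)), 180.0))


@dataclass
class ModelFit:
    """Result of maximum-likelihood fitting one track."""

    params: ModelParams
    params_se: dict
    neg_loglik: float
    converged: bool
    diagnostics: dict
    track: Track            # full track (keep mask intact)
    estimate_psi: bool
    fix_rho_at_zero: bool
    ls_table: Optional[LsErrorTable]


def build_transition(delta: float, D: float):
    """Transition matrix and process covariance over an interval of ``delta`` h.

    Both coordinate axes share D and are independent; position/velocity
    process noise is correlated because the position update uses the new
    velocity (Q has the rank-1 outer-product form per axis).
    """
    if delta < 0:
        raise RuntimeError(f"negative time increment {delta} (ordering bug upstream)")
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    d = float(delta)
    T = np.eye(4)
    T[0, 2] = d
    T[1, 3] = d
    q = 2.0 * D * d
    Q = np.zeros((4, 4))
    Q[0, 0] = Q[1, 1] = q * d * d
    Q[2, 2] = Q[3, 3] = q
    Q[0, 2] = Q[2, 0] = Q[1, 3] = Q[3, 1] = q * d
    return T, Q


def build_omegas(track: Track, params: ModelParams,
                 ls_table: Optional[LsErrorTable] = None) -> np.ndarray:
    """Per-observation measurement covariances (n, 2, 2) for a track."""
    if track.datatype == "LS":
        if ls_table is None:
            ls_table = LsErrorTable.from_yaml()
        if track.lc is None:
            raise ValueError("LS track has no location classes")
        return np.atleast_3d(
            ls_cov(track.lc, params.tau_x, params.tau_y,
                   0.0 if params.rho is None else params.rho, ls_table)
        ).reshape(len(track), 2, 2)
    if track.datatype in ("KF", "KS"):
        psi = 1.0 if params.psi is None else params.psi
        cov = ellipse_to_cov(track.smaj, track.smin, track.eor, psi=psi)
        return cov.reshape(len(track), 2, 2)
    raise ValueError(f"cannot build measurement covariances for datatype {track.datatype}")


def _initial_moments(y0: np.ndarray):
    m0 = np.array([y0[0], y0[1], 0.0, 0.0])
    P0 = np.diag([KAPPA_POS, KAPPA_POS, KAPPA_VEL, KAPPA_VEL])
    return m0, P0


def kalman_filter(t_hours: np.ndarray, obs: np.ndarray, omegas: np.ndarray,
                  D: float, m0: np.ndarray, P0: np.ndarray):
    """Kalman filter over an irregular time grid with possibly-missing rows.

    obs is (n, 2); NaN rows are treated as missing (prediction only).
    Returns (neg_loglik, filtered means, filtered covs, predicted means,
    predicted covs). neg_loglik is +inf if an innovation covariance goes
    non-finite or singular (optimizer-safe).
    """
    n = len(t_hours)
    mf = np.empty((n, 4))
    Pf = np.empty((n, 4, 4))
    mp = np.empty((n, 4))
    Pp = np.empty((n, 4, 4))
    nll = 0.0
    m, P = m0, P0
    for i in range(n):
        if i > 0:
            d = t_hours[i] - t_hours[i - 1]
            T, Q = build_transition(d, D)
            m = T @ m
            P = T @ P @ T.T + Q
        mp[i] = m
        Pp[i] = P
        yi = obs[i]
        if np.all(np.isfinite(yi)):
            S = P[:2, :2] + omegas[i]
            det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
            if not np.isfinite(det) or det <= 0:
                logger.debug("non-PD innovation covariance at step %d", i)
                return np.inf, mf, Pf, mp, Pp
            nu = yi - m[:2]
            Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
            nll += 0.5 * (2.0 * _LOG2PI + np.log(det) + nu @ Sinv @ nu)
            K = P[:, :2] @ Sinv
            m = m + K @ nu
            P = P - K @ P[:2, :]
            P = 0.5 * (P + P.T)
        mf[i] = m
        Pf[i] = P
    if not np.isfinite(nll):
        return np.inf, mf, Pf, mp, Pp
    return float(nll), mf, Pf, mp, Pp


def rts_smoother(t_hours: np.ndarray, mf, Pf, mp, Pp, D: float):
    """Fixed-interval RTS backward pass; returns smoothed means and covs."""
    n = len(t_hours)
    ms = mf.copy()
    Ps = Pf.copy()
    for i in range(n - 2, -1, -1):
        d = t_hours[i + 1] - t_hours[i]
        T, _ = build_transition(d, D)
        # gain J = Pf[i] T' Pp[i+1]^{-1}
        J = np.linalg.solve(Pp[i + 1].T, (Pf[i] @ T.T).T).T
        ms[i] = mf[i] + J @ (ms[i + 1] - mp[i + 1])
        Ps[i] = Pf[i] + J @ (Ps[i + 1] - Pp[i + 1]) @ J.T
        Ps[i] = 0.5 * (Ps[i] + Ps[i].T)
    return ms, Ps


# ---------------------------------------------------------------------------
# parameter packing

def _active_names(datatype: str, estimate_psi: bool, fix_rho: bool) -> list[str]:
    if datatype == "LS":
        names = ["D", "tau_x", "tau_y"]
        if not fix_rho:
            names.append("rho")
        return names
    if datatype in ("KF", "KS"):
        return ["D", "psi"] if estimate_psi else ["D"]
    raise ValueError(f"unsupported datatype for fitting: {datatype}")


def _to_transformed(params: ModelParams, names) -> np.ndarray:
    out = []
    for nm in names:
        v = getattr(params, nm)
        out.append(np.arctanh(v) if nm == "rho" else np.log(v))
    return np.array(out)


def _from_transformed(eta: np.ndarray, names, datatype: str,
                      estimate_psi: bool, fix_rho: bool) -> ModelParams:
    vals = {}
    for nm, e in zip(names, eta):
        vals[nm] = float(np.tanh(e)) if nm == "rho" else float(np.exp(e))
    p = ModelParams(D=vals["D"])
    if datatype == "LS":
        p.tau_x = vals["tau_x"]
        p.tau_y = vals["tau_y"]
        p.rho = 0.0 if fix_rho else vals["rho"]
    elif datatype in ("KF", "KS"):
        p.psi = vals["psi"] if estimate_psi else 1.0
    return p


def negloglik(params: ModelParams, track: Track,
              ls_table: Optional[LsErrorTable] = None) -> float:
    """Exact negative log-likelihood of the retained observations."""
    sub = track.retained()
    omegas = build_omegas(sub, params, ls_table)
    obs = np.column_stack([sub.x, sub.y])
    m0, P0 = _initial_moments(obs[0])
    nll, *_ = kalman_filter(sub.t_hours, obs, omegas, params.D, m0, P0)
    return nll


def fit(track: Track, estimate_psi: bool = True, fix_rho_at_zero: bool = False,
        min_obs: int = 10, start: Optional[ModelParams] = None,
        ls_table: Optional[LsErrorTable] = None) -> ModelFit:
    """Maximum-likelihood fit of the movement and measurement parameters.

    Deterministic given the documented fixed initialization (D = 0.1
    km^2 h^-3, tau = 1 km, rho = 0, psi = 1); optimizer failures degrade
    gracefully to a non-converged ModelFit holding the best point found.
    """
    sub = track.retained()
    if len(sub) < min_obs:
        raise ValueError(
            f"track {track.id!r} has {len(sub)} retained fixes; need >= {min_obs}"
        )
    names = _active_names(track.datatype, estimate_psi, fix_rho_at_zero)
    if start is None:
        start = ModelParams(D=0.1, tau_x=1.0, tau_y=1.0, rho=0.0, psi=1.0)
    eta0 = _to_transformed(start, names)

    if ls_table is None and track.datatype == "LS":
        ls_table = LsErrorTable.from_yaml()

    def objective(eta):
        p = _from_transformed(eta, names, track.datatype, estimate_psi, fix_rho_at_zero)
        try:
            return negloglik(p, track, ls_table)
        except (ValueError, np.linalg.LinAlgError):
            return np.inf

    res = minimize(objective, eta0, method="L-BFGS-B",
                   options={"ftol": 1e-8, "gtol": 1e-6, "maxiter": 500})
    eta_hat = res.x
    params = _from_transformed(eta_hat, names, track.datatype,
                               estimate_psi, fix_rho_at_zero)
    converged = bool(res.success) and np.isfinite(res.fun)

    params_se: dict = {}
    if converged:
        try:
            H = approx_hess(eta_hat, objective)
            Hinv = np.linalg.inv(H)
            if np.all(np.diag(Hinv) > 0):
                se_eta = np.sqrt(np.diag(Hinv))
                for nm, eta_i, se_i in zip(names, eta_hat, se_eta):
                    if nm == "rho":
                        params_se[nm] = float((1.0 - np.tanh(eta_i) ** 2) * se_i)
                    else:
                        params_se[nm] = float(np.exp(eta_i) * se_i)
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False

    return ModelFit(
        params=params,
        params_se=params_se,
        neg_loglik=float(res.fun),
        converged=converged,
        diagnostics={"message": str(res.message), "nit": int(res.nit),
                     "nfev": int(res.nfev), "optimizer_success": bool(res.success)},
        track=track,
        estimate_psi=estimate_psi,
        fix_rho_at_zero=fix_rho_at_zero,
        ls_table=ls_table,
    )


def _smooth_on_grid(fitres: ModelFit, t_union: np.ndarray, obs_mask: np.ndarray):
    """Run filter + RTS smoother on a grid where only some times have data."""
    sub = fitres.track.retained()
    omegas_obs = build_omegas(sub, fitres.params, fitres.ls_table)
    n = len(t_union)
    obs = np.full((n, 2), np.nan)
    omegas = np.zeros((n, 2, 2))
    obs[obs_mask] = np.column_stack([sub.x, sub.y])
    omegas[obs_mask] = omegas_obs
    m0, P0 = _initial_moments(obs[np.flatnonzero(obs_mask)[0]])
    nll, mf, Pf, mp, Pp = kalman_filter(t_union, obs, omegas, fitres.params.D, m0, P0)
    if not np.isfinite(nll):
        raise RuntimeError("non-finite likelihood at the fitted parameters")
    return rts_smoother(t_union, mf, Pf, mp, Pp, fitres.params.D)


def _make_estimates(times: pd.DatetimeIndex, ms, Ps) -> list[StateEstimate]:
    return [
        StateEstimate(t=t, x=float(m[0]), y=float(m[1]),
                      vx=float(m[2]), vy=float(m[3]), cov=P)
        for t, m, P in zip(times, ms, Ps)
    ]


def smooth(fitres: ModelFit) -> list[StateEstimate]:
    """Fitted locations: smoothed states at the retained observation times."""
    sub = fitres.track.retained()
    t = sub.t_hours
    ms, Ps = _smooth_on_grid(fitres, t, np.ones(len(t), dtype=bool))
    return _make_estimates(sub.times, ms, Ps)


def predict(fitres: ModelFit, interval_hours: float = 2.0,
            return_fitted: bool = False):
    """Predicted locations on a regular grid from first to last retained fix.

    The smoother runs once on the union of observation and grid times and
    estimates are reported at the grid times only; with
    ``return_fitted=True`` the same pass also returns the states at the
    observation times, which by construction agree exactly with the grid
    states wherever the two sets of times coincide. (Because the process
    model is defined on the time grid actually used, inserting prediction
    times perturbs the observation-time states very slightly relative to
    :func:`smooth`; see the methods note.) Grids finer than 1 s are refused:
    over-fine grids inflate the state dimension for no information gain and
    invite convergence trouble.
    """
    if interval_hours <= 0:
        raise ValueError(f"interval must be > 0 h, got {interval_hours}")
    if interval_hours < 1.0 / 3600.0:
        raise ValueError(f"prediction interval {interval_hours} h is finer than 1 s")
    sub = fitres.track.retained()
    t_obs = sub.t_hours
    span = t_obs[-1] - t_obs[0]
    grid = np.arange(0.0, span, interval_hours)
    grid = np.append(grid, span)  # always include the final observation time
    t_union = np.union1d(np.round(t_obs, 12), np.round(grid, 12))
    obs_mask = np.isin(t_union, np.round(t_obs, 12))
    grid_mask = np.isin(t_union, np.round(grid, 12))
    ms, Ps = _smooth_on_grid(fitres, t_union, obs_mask)
    t0 = sub.times[0]
    times = pd.DatetimeIndex(
        [t0 + pd.Timedelta(seconds=h * 3600.0) for h in t_union[grid_mask]]
    )
    grid_estimates = _make_estimates(times, ms[grid_mask], Ps[grid_mask])
    if not return_fitted:
        return grid_estimates
    fitted = _make_estimates(sub.times, ms[obs_mask], Ps[obs_mask])
    return grid_estimates, fitted
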