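"""Per-observation measurement covariances for Argos location data.

Two measurement models are supported, matching the two ways Argos reports
location quality:

* **Error ellipses** (Kalman filter / Kalman smoother service data): each fix
  carries a semi-major axis M, semi-minor axis m and an orientation c of the
  semi-major axis measured clockwise from north. The 2x2 covariance over
  (east, north) is the rotated diagonal ellipse covariance with the axes
  scaled by 1/sqrt(2), and with a single global inflation factor ``psi``
  applied to every reported semi-minor axis. psi > 1 widens the uncertainty
  region in the across-ellipse (generally north-south) direction, correcting
  the systematic underestimation of the reported semi-minor axes.

* **Quality classes** (Least-Squares service data): classes 3,2,1,0,A,B carry
  no quantitative uncertainty. Base scales tau_x, tau_y (estimated during
  model fitting) are multiplied by per-class weighting factors K_x, K_y
  (ratios of each class's SE to class 3); rho correlates the two axes.

All lengths here are km.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

LS_CLASSES = ("3", "2", "1", "0", "A", "B")


@dataclass(frozen=True)
class LsErrorTable:
    """Per-class SE ratios to class 3, per axis (K_x east, K_y north)."""

    k_x: Mapping[str, float]
    k_y: Mapping[str, float]

    def __post_init__(self):
        for cls in LS_CLASSES:
            if cls not in self.k_x or cls not in self.k_y:
                raise ValueError(f"LS error table missing class {cls!r}")
        if not (self.k_x["3"] == 1.0 and self.k_y["3"] == 1.0):
            raise ValueError("class-3 weighting factors must equal 1")
        if any(v < 1.0 for v in (*self.k_x.values(), *self.k_y.values())):
            raise ValueError("weighting factors must be >= 1")

    @classmethod
    def from_yaml(cls, path=None) -> "LsErrorTable":
        """Load a table from YAML; the packaged default when path is None."""
        if path is None:
            ref = importlib.resources.files("argosqc.data") / "ls_error_table.yaml"
            raw = yaml.safe_load(ref.read_text())
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        return cls(
            k_x={str(k): float(v["K_x"]) for k, v in raw.items()},
            k_y={str(k): float(v["K_y"]) for k, v in raw.items()},
        )


def ellipse_to_cov(M, m, c_deg, psi: float = 1.0):
    """Covariance (km^2) of one fix from its error-ellipse parameters.

    Parameters
    ----------
    M, m : array-like
        Semi-major and semi-minor axis lengths, km, with M >= m > 0.
    c_deg : array-like
        Orientation of the semi-major axis, degrees clockwise from north,
        in [0, 180).
    psi : float
        Global semi-minor-axis inflation factor (> 0); 1 uses the reported
        ellipse as-is.

    Returns
    -------
    ndarray
        2x2 covariance (scalar input) or (n, 2, 2) stack, over (east, north).

    Notes
    -----
    With s = sin(c), co = cos(c):

    * var_east  = (M/sqrt2)^2 s^2 + (m psi/sqrt2)^2 co^2
    * var_north = (M/sqrt2)^2 co^2 + (m psi/sqrt2)^2 s^2
    * cov       = ((M^2 - m^2 psi^2)/2) co s

    so the eigenvalues are exactly {(M/sqrt2)^2, (m psi/sqrt2)^2} for any c.
    If an estimated psi makes m*psi exceed M the covariance remains valid
    (the eigenvalue roles swap); no clamping is applied.
    """
    M = np.asarray(M, dtype=float)
    m = np.asarray(m, dtype=float)
    c_deg = np.asarray(c_deg, dtype=float)
    scalar = M.ndim == 0 and m.ndim == 0 and c_deg.ndim == 0
    M, m, c_deg = np.atleast_1d(M, m, c_deg)
    if psi <= 0:
        raise ValueError(f"psi must be > 0, got {psi}")
    bad = ~((M >= m) & (m > 0))
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"invalid ellipse at record {i}: M={M[i]}, m={m[i]} (need M >= m > 0)"
        )
    bad_c = ~((c_deg >= 0) & (c_deg < 180))
    if np.any(bad_c):
        i = int(np.flatnonzero(bad_c)[0])
        raise ValueError(f"orientation out of [0,180) at record {i}: c={c_deg[i]}")

    c = np.radians(c_deg)
    s2, co2 = np.sin(c) ** 2, np.cos(c) ** 2
    a2 = (M / np.sqrt(2.0)) ** 2
    b2 = (m * psi / np.sqrt(2.0)) ** 2
    var_x = a2 * s2 + b2 * co2
    var_y = a2 * co2 + b2 * s2
    cov_xy = (M**2 - (m * psi) ** 2) / 2.0 * np.cos(c) * np.sin(c)

    out = np.empty(M.shape + (2, 2))
    out[..., 0, 0] = var_x
    out[..., 1, 1] = var_y
    out[..., 0, 1] = cov_xy
    out[..., 1, 0] = cov_xy
    return out[0] if scalar else out


def ls_cov(lc, tau_x: float, tau_y: float, rho: float, table: LsErrorTable):
    """Covariance (km^2) for Least-Squares fixes from their quality classes.

    tau_x, tau_y are the class-3 SDs (km) on the east/north axes, scaled per
    class by the table's weighting factors; rho in (-1, 1) is the correlation
    between the two axes (shared across classes).
    """
    if not (tau_x > 0 and tau_y > 0):
        raise ValueError(f"tau must be > 0, got ({tau_x}, {tau_y})")
    if not (-1.0 < rho < 1.0):
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    lc_arr = np.atleast_1d(np.asarray(lc, dtype=object))
    scalar = np.asarray(lc, dtype=object).ndim == 0
    unknown = [str(c) for c in lc_arr if str(c) not in table.k_x]
    if unknown:
        raise ValueError(
            f"unknown location class(es) {sorted(set(unknown))} after class-Z policy"
        )
    kx = np.array([table.k_x[str(c)] for c in lc_arr])
    ky = np.array([table.k_y[str(c)] for c in lc_arr])
    sx = tau_x * kx
    sy = tau_y * ky
    out = np.empty((len(lc_arr), 2, 2))
    out[:, 0, 0] = sx**2
    out[:, 1, 1] = sy**2
    out[:, 0, 1] = rho * sx * sy
    out[:, 1, 0] = out[:, 0, 1]
    return out[0] if scalar else out
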