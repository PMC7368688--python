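# argosqc

Quality control of Argos satellite animal-tracking data with a
continuous-time state-space model.

Argos locations — whether legacy Least-Squares fixes carrying only an
ordinal quality class (3, 2, 1, 0, A, B, Z) or modern Kalman filter/smoother
fixes carrying an error ellipse — are error-prone and irregularly timed.
Near real-time uses of these data (dynamic ocean management, assimilation of
animal-borne sensor profiles into ocean forecasts) need automated, reliable
filtering. `argosqc` implements a deliberately simple model for that job:

* **Process model** — a continuous-time random walk on velocity with a
  single diffusion coefficient *D* (km² h⁻³):

      v_i = v_{i-1} + η_i,        η_i ~ N(0, 2 D Δ_i)   per axis
      x_i = x_{i-1} + v_i Δ_i

  where Δ_i is the (irregular) elapsed time between fixes, in hours.

* **Measurement model** — observed locations y_i = x_i + ε_i with
  ε_i ~ N(0, Ω_i). For error-ellipse data, Ω_i is built from the reported
  semi-major axis M_i, semi-minor axis m_i and orientation c_i, with a
  single estimated inflation ψ that re-scales every semi-minor axis
  (ψ > 1 widens the uncertainty region in the generally north–south
  direction, where Argos ellipses are systematically too narrow). For
  Least-Squares data, per-class error weighting factors scale estimated base
  SDs τ_x, τ_y with correlation ρ.

* **Inference** — the model is linear-Gaussian, so the likelihood is exact
  (Kalman prediction-error decomposition over the irregular time grid) and
  is maximised by quasi-Newton search over log/atanh-transformed
  parameters. The RTS smoother produces *fitted* locations at the
  observation times and *predicted* locations on a regular grid
  (default 2 h), each with 95% confidence ellipses.

The package also ships a travel-rate pre-filter (iterative both-neighbours
speed screening at, e.g., 3 m s⁻¹ for pinnipeds and turtles, 17 m s⁻¹ for
gannets), a synthetic double-tagging simulator (Argos + GPS on one animal),
and GPS validation metrics (RMSD, log-difference of RMSDs between methods).
All modelling happens in km on the WGS84 World Mercator plane (EPSG:3395);
distances and travel rates use WGS84 geodesics.

## Worked example

```python
from argosqc import simulate, prefilter, ssm_core, validate

# a 10-day synthetic animal: Argos KF fixes (30-min mean gaps) whose reported
# semi-minor axes are 1.5x too small, plus 15-min GPS truth
cfg = simulate.SimConfig(seed=1, m_shrink=1.5, outlier_rate=0.02)
truth, argos, gps = simulate.simulate_double_tagged(cfg)

argos = prefilter.apply_filter(argos, prefilter.speed_filter(argos, vmax=3.0))
fit = ssm_core.fit(argos)                 # ML estimates of D and psi
print(fit.params.D, fit.params.psi)       # 0.0518 1.3843  (true: 0.05, 1.5)

fitted = ssm_core.smooth(fit)             # states at the observation times
r = validate.validate_estimates(fitted, gps, track_id="sim")
print(r.rmsd_km)                          # 0.4486 km vs interpolated GPS

raw, model, ld = validate.compare_smoothed_vs_raw(argos, gps)
print(raw.rmsd_km, model.rmsd_km, ld)     # 3.2516 0.4486 -1.9808
```

The fitted diffusion and ellipse-inflation land within a couple of standard
errors of the generator's truth; smoothing cuts the RMSD against GPS from
3.25 km (pre-filtered raw fixes) to 0.45 km, a log-difference of −1.98.

The same pipeline is scriptable from a shell:

```sh
argosqc simulate --seed 1 --n-animals 5 --outdir sim/
argosqc fit --input sim/argos.csv --datatype KF --vmax 3 --outdir fit/
argosqc validate --estimates fit/fitted.csv --gps sim/gps.csv --outdir val/
```

`fit/` contains `fitted.csv`, `predicted.csv` (2-h grid) and a JSON run
report with per-animal parameter estimates, convergence flags and the
fraction of fixes removed by the pre-filter; one failing animal never aborts
the batch.

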