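# Methods

## Model

Animal movement is modelled as a continuous-time random walk on velocity.
Over an elapsed interval Δ (hours) each velocity component receives an
independent zero-mean Gaussian increment with variance 2DΔ; the single
diffusion coefficient D (km² h⁻³) is the only process parameter. Position
integrates velocity with the post-increment value,

    x_i = x_{i-1} + v_i Δ_i,

so the per-axis process covariance of the stacked (position, velocity)
state over one interval is the rank-one matrix

    Q(Δ) = 2DΔ · [[Δ², Δ], [Δ, 1]].

Both axes share D and are independent a priori; correlation between
observed locations arises from integrating the common velocity process.

Observed locations are y_i = x_i + ε_i, ε_i ~ N(0, Ω_i), with Ω_i depending
on the data flavour:

* **Error-ellipse data** (Argos Kalman filter/smoother service). With
  semi-major axis M, semi-minor axis m (km) and orientation c (degrees
  clockwise from north),

      τ_x² = (M/√2)² sin²c + (mψ/√2)² cos²c
      τ_y² = (M/√2)² cos²c + (mψ/√2)² sin²c
      τ_xy = ((M² − m²ψ²)/2) · cos c · sin c

  so the covariance eigenvalues are exactly {(M/√2)², (mψ/√2)²}. The global
  inflation ψ > 0 re-scales every reported semi-minor axis; estimates above
  1 correct the systematic narrowness of reported ellipses in the
  across-ellipse (generally north–south) direction. ψ is one parameter per
  fit, estimated on the log scale with no upper constraint; if an estimate
  ever made mψ > M the covariance would remain valid (the eigenvalue roles
  swap), so no clamping is applied.

* **Quality-class data** (Least-Squares service). Classes carry no
  quantitative uncertainty, so base SDs τ_x, τ_y (km; the class-3 scales)
  and the cross-axis correlation ρ are estimated, and per-class weighting
  factors K_x, K_y ≥ 1 — SE ratios of each class to class 3 per axis —
  scale them. The shipped factor table derives from the captive-seal
  calibration literature and is an editable YAML data file
  (`argosqc/data/ls_error_table.yaml`), not a code constant; studies with
  their own calibration should override it. ρ is estimated through an
  atanh transform by default, with an option to fix it at zero. Class Z
  fixes carry essentially no information; the reader either relabels them
  as class B (default) or drops them — both policies are exposed because
  common practice varies.

## Estimation

The model is linear-Gaussian, so the Laplace-approximation machinery often
used for this model family is exact here, and the implementation uses the
exact equivalent directly: a Kalman filter over the irregular observation
times supplies the likelihood by prediction-error decomposition, and the
fixed-interval RTS smoother supplies state estimates conditioned on the
whole track. A brute-force oracle (explicit joint-Gaussian marginalization
of the latent states on tiny tracks) verifies both to ~1e-11 relative error
in the test suite.

Numerical choices:

* **Initialization.** Diffuse-but-proper prior on the first state: centred
  on the first observation with zero velocity, variances 1e6 km² on
  positions and 1e4 (km/h)² on velocities. The regression test for "diffuse
  enough" is translation invariance of the likelihood.
* **Parameter transforms and starts.** log D, log τ_x, log τ_y, atanh ρ,
  log ψ; deterministic starts D = 0.1 km² h⁻³, τ = 1 km, ρ = 0, ψ = 1.
  No random restarts, so fits are reproducible byte-for-byte.
* **Optimizer.** L-BFGS-B with ftol 1e-8, gtol 1e-6. Non-convergence never
  raises: the automated-QC use case demands graceful degradation, so a
  non-converged `ModelFit` carries the best point found and a flag.
* **Uncertainty.** Parameter SEs by the delta method from the numerical
  Hessian of the negative log-likelihood in transformed space; they are
  reported only when that Hessian is positive definite. State SEs come
  from the smoother covariance; lon/lat SEs and 95% confidence ellipses
  linearize the inverse Mercator at the estimate.
* **Degenerate inputs.** A non-positive-definite innovation covariance
  returns +inf (optimizer-safe). Duplicate timestamps are perturbed
  forward in 10-s steps at ingest (recorded in a provenance column); the
  resulting tiny Δ keeps Q positive semi-definite by construction.

### Grid dependence of the printed process model

The position update x_i = x_{i-1} + v_i Δ_i is a discretization that is not
consistent under refinement of the time grid: splitting an interval in two
changes the implied position process variance (2D·5Δ³ versus 2D·8Δ³ for a
halved step). The model is therefore defined on the grid actually used.
Consequences adopted here:

* The likelihood and the *fitted* locations (`smooth`) are defined on the
  observation times alone — this is also what the brute-force oracle
  verifies, and what GPS validation consumes.
* *Predicted* locations (`predict`) come from one smoothing pass on the
  union of observation and regular grid times, reported at grid times;
  `return_fitted=True` returns the observation-time states from that same
  pass, which agree exactly with grid states at coincident times.
  Observation-time states from the union pass differ from `smooth` output
  at the tens-of-metres scale for typical tracks (asserted < 0.5 km in the
  tests) — far below the km-scale measurement uncertainty.
* Prediction grids finer than 1 s are refused; over-fine grids inflate the
  state dimension for no information gain and invite convergence trouble.

## Pre-filter

Before fitting, fixes implying impossible sustained travel rates are
flagged (never deleted, so removal fractions stay reportable). An interior
fix is removable only when the implied speeds to BOTH currently retained
neighbours exceed the threshold — removing on a single fast leg would
delete the good neighbour of an outlier. The worst offender (ties: earlier
index) is removed first and speeds recomputed, until no removable fix
remains; endpoints are never removed. Speeds use WGS84 geodesic distances
on geographic coordinates, since the filter runs before projection and
Mercator distorts distance with latitude. Defaults: 3 m s⁻¹
(pinnipeds/turtles), 17 m s⁻¹ (gannets). The filter is idempotent, and
raising the threshold never removes more fixes.

Adjacent outliers displaced in nearly the same direction can mutually
shield each other under the both-neighbours rule; with independent outlier
directions this is rare (the measured sensitivity on planted 100-km
outliers is ~96–99%), but it is a known limitation of this filter family.

## Geometry

Projection is the WGS84 World Mercator (EPSG:3395), implemented from the
ellipsoidal closed forms with an iterative latitude inverse (round-trip
< 1e-9°); coordinates are divided by 1000 so all model quantities are km.
Latitudes beyond ±89.9° raise rather than clamp, because silent clamping
corrupts distances. Tracks crossing the antimeridian are unwrapped per
track before projection (consecutive fixes forced within 180°) and
re-wrapped on output; how the original study handled such tracks is not
stated, so this is this package's own rule. Geodesic distances use the
Vincenty inverse with a haversine fallback for the rare non-convergent
near-antipodal pairs.

## Synthetic double-tagging generator

The generator exists so every pipeline stage is testable without field
data. It simulates the latent process exactly on the union of all sampling
times (no discretization error), then observes it two ways:

* **Argos**: irregular times (exponential gaps, default mean 30 min, 1-min
  floor; or a regular grid). Error-ellipse mode draws M lognormal (median
  5 km, log-SD 0.6), shape ratio m/M ~ Beta(2, 8) (mean 0.2, matching
  typical reported shape medians of 0.13–0.27), and orientation c normal
  around 90° (SD 25°, wrapped) — east–west elongated ellipses, i.e. lower
  north–south uncertainty, as polar-orbiting geometry produces. Errors are
  drawn with the TRUE covariance; the REPORTED semi-minor axis is the true
  one divided by `m_shrink`, so the fitted ψ should recover `m_shrink`
  exactly — the measurement model's reading of ψ is the inverse of the
  generator's distortion. Quality-class mode draws classes from a mixture
  (default 70% A/B, in the range seen for diving species) with per-class
  SDs from the weighting table scaled by base SDs (0.30/0.25 km).
  Gross outliers occur at a configurable rate (default 1%), displacing the
  fix by a fixed distance (default 100 km) in a uniform direction while
  leaving the reported metadata unchanged — the "vastly underestimated
  error ellipse" phenomenon.
* **GPS**: a regular grid (default 15 min, offset half a gap so GPS and
  Argos times interleave), isotropic noise SD 0.03 km.

Defaults (10-day tracks, D = 0.05 km² h⁻³ giving ~1 m s⁻¹ RMS speeds,
mid-latitude start) are the package's reference study conditions. What the
generator does **not** emulate: satellite-pass geometry and
surfacing-driven sampling, class assignment from message counts,
heavy-tailed (non-Gaussian) errors, prolonged multi-day gaps, and
behaviour-switching movement. Passing tests therefore demonstrate
correctness of the machinery and self-consistency of the model family, not
performance on any particular real deployment.

## Validation metrics

Model-estimated locations are compared with GPS assumed true, either by
linear interpolation of the GPS track (per coordinate, in the projected
plane) to the estimate times, or by pairing with the temporally closest GPS
fix within ±10 min (ties: smaller time difference, then earlier fix; GPS
fixes may be reused; out-of-span times are dropped, never extrapolated).
Per-track accuracy is RMSD (km) over pairs, with distances measured as
WGS84 geodesics; two schemes are compared by log RMSD difference, which
approximates their fractional accuracy difference. The two experiment
drivers — ψ-on versus ψ-off, and model-fitted versus pre-filtered raw
locations — hold everything else fixed (same pre-filter mask, same times,
same pair counts in both arms).

## Problem sizes

The shipped experiments use tracks of ~480–500 Argos fixes; 25–50
replicates for parameter recovery, 10–20 for the ψ experiment, 15–25 for
the smoothing comparison, and 15–20 for the pre-filter operating
characteristics. These sizes give Monte-Carlo error comfortably below the
effect sizes being checked while keeping a full run to a couple of minutes
on one CPU. The pre-filter experiment uses its own conditions — regular
hourly fixes, D = 0.015 km² h⁻³ (a slow, ~0.6 m s⁻¹ RMS animal) and
seal-like ellipse scales (median semi-major axis 1.5 km) with 5% planted
100-km outliers — so that genuine measurement noise at hourly gaps cannot
imply >3 m s⁻¹ travel on both legs and the filter's sensitivity and
false-removal rate are measured against a clean planted truth.

## Known limitations

* Single D shared by both axes and all behaviours; no move-persistence or
  behavioural switching. This is a deliberate speed/reliability trade-off.
* The Gaussian measurement model relies on the pre-filter to catch gross
  outliers; a heavy-tailed measurement distribution is out of scope.
* The Least-Squares weighting table is a calibration transplanted from
  captive-seal data; per-study recalibration is encouraged.
* Grid dependence of the printed discretization (above) means predicted
  tracks depend mildly on the chosen prediction interval.
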