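import numpy as np
import pandas as pd
import pytest

from argosqc import ssm_core
from argosqc.ssm_core import (ModelParams, build_transition, fit, negloglik,
                              predict, smooth)
from conftest import make_plane_track
from oracles import negloglik_bruteforce, smooth_bruteforce


def random_small_track(rng, n=None):
    """Tiny random KF track plus everything the oracle needs."""
    n = n or int(rng.integers(2, 6))
    t = np.sort(rng.uniform(0.0, 24.0, size=n))
    t[0] = 0.0
    while np.any(np.diff(t) < 1e-3):
        t = np.sort(rng.uniform(0.0, 24.0, size=n))
        t[0] = 0.0
    x = np.cumsum(rng.normal(0.0, 2.0, size=n))
    y = np.cumsum(rng.normal(0.0, 2.0, size=n))
    M = rng.uniform(1.0, 8.0, size=n)
    m = M * rng.uniform(0.1, 1.0, size=n)
    c = rng.uniform(0.0, 180.0, size=n) % 180.0
    track = make_plane_track(x, y, t, datatype="KF", smaj=M, smin=m, eor=c)
    return track


def oracle_inputs(track, params):
    sub = track.retained()
    omegas = ssm_core.build_omegas(sub, params)
    obs = np.column_stack([sub.x, sub.y])
    m0, P0 = ssm_core._initial_moments(obs[0])
    return sub.t_hours, obs, omegas, m0, P0


class TestBuildTransition:
    def test_zero_interval_is_identity_with_no_noise(self):
        T, Q = build_transition(0.0, 0.05)
        assert np.allclose(T, np.eye(4))
        assert np.allclose(Q, 0.0)

    def test_unit_interval_entries(self):
        # 2*D*Delta = 0.1 fills velocity, position and cross entries at Delta=1
        _, Q = build_transition(1.0, 0.05)
        assert Q[2, 2] == pytest.approx(0.1)
        assert Q[0, 0] == pytest.approx(0.1)
        assert Q[0, 2] == pytest.approx(0.1)
        assert Q[0, 1] == 0.0 and Q[2, 3] == 0.0  # axes independent

    def test_process_noise_is_rank_one_per_axis(self, rng):
        for _ in range(25):
            d, D = rng.uniform(0.01, 30.0), rng.uniform(1e-3, 1.0)
            _, Q = build_transition(d, D)
            qx = Q[np.ix_([0, 2], [0, 2])]
            assert np.allclose(qx, 2 * D * d * np.outer([d, 1.0], [d, 1.0]))
            assert np.linalg.eigvalsh(qx)[0] >= -1e-12

    def test_negative_interval_is_internal_error(self):
        with pytest.raises(RuntimeError, match="ordering"):
            build_transition(-0.5, 0.05)


class TestNegloglik:
    def test_matches_bruteforce_on_three_observations(self, rng):
        track = random_small_track(rng, n=3)
        params = ModelParams(D=0.07, psi=1.2)
        got = negloglik(params, track)
        want = negloglik_bruteforce(*oracle_inputs(track, params)[:3],
                                    params.D, *oracle_inputs(track, params)[3:])
        assert got == pytest.approx(want, rel=1e-8)

    def test_changing_psi_changes_value(self, rng):
        track = random_small_track(rng, n=5)
        a = negloglik(ModelParams(D=0.05, psi=1.0), track)
        b = negloglik(ModelParams(D=0.05, psi=2.0), track)
        assert a != b

    def test_translation_invariance(self, rng):
        # a diffuse prior centred on the first fix makes the likelihood
        # invariant to translating the whole track
        track = random_small_track(rng, n=5)
        shifted = make_plane_track(track.x + 500.0, track.y - 300.0,
                                   track.t_hours, datatype="KF",
                                   smaj=track.smaj, smin=track.smin, eor=track.eor)
        p = ModelParams(D=0.05, psi=1.3)
        assert negloglik(p, track) == pytest.approx(negloglik(p, shifted), rel=1e-9)


class TestSmooth:
    def test_matches_bruteforce_conditional_moments(self, rng):
        for _ in range(10):
            track = random_small_track(rng)
            params = ModelParams(D=0.08, psi=1.1)
            t, obs, omegas, m0, P0 = oracle_inputs(track, params)
            want_m, want_P = smooth_bruteforce(t, obs, omegas, params.D, m0, P0)
            nll, mf, Pf, mp, Pp = ssm_core.kalman_filter(t, obs, omegas, params.D, m0, P0)
            got_m, got_P = ssm_core.rts_smoother(t, mf, Pf, mp, Pp, params.D)
            assert np.allclose(got_m, want_m, rtol=1e-8, atol=1e-8)
            assert np.allclose(got_P, want_P, rtol=1e-6, atol=1e-8)

    def test_noiseless_limit_recovers_observations(self, rng):
        track = random_small_track(rng, n=5)
        track.smaj[:] = 1e-4
        track.smin[:] = 1e-4
        params = ModelParams(D=0.05, psi=1.0)
        t, obs, omegas, m0, P0 = oracle_inputs(track, params)
        _, mf, Pf, mp, Pp = ssm_core.kalman_filter(t, obs, omegas, params.D, m0, P0)
        ms, _ = ssm_core.rts_smoother(t, mf, Pf, mp, Pp, params.D)
        assert np.allclose(ms[:, :2], obs, atol=1e-3)

    def test_smoother_never_less_certain_than_filter(self, rng):
        track = random_small_track(rng, n=5)
        params = ModelParams(D=0.05, psi=1.0)
        t, obs, omegas, m0, P0 = oracle_inputs(track, params)
        _, mf, Pf, mp, Pp = ssm_core.kalman_filter(t, obs, omegas, params.D, m0, P0)
        _, Ps = ssm_core.rts_smoother(t, mf, Pf, mp, Pp, params.D)
        for i in range(len(t)):
            assert (np.diag(Ps[i]) <= np.diag(Pf[i]) + 1e-9).all()


class TestFit:
    def test_constant_position_track_gives_small_diffusion(self, rng):
        n = 30
        t = np.arange(n, dtype=float)
        x = 100.0 + rng.normal(0, 1e-3, n)
        y = -50.0 + rng.normal(0, 1e-3, n)
        track = make_plane_track(x, y, t, datatype="KF",
                                 smaj=np.full(n, 0.05), smin=np.full(n, 0.05),
                                 eor=np.full(n, 90.0))
        f = fit(track, estimate_psi=False)
        assert f.params.D < 1e-3
        est = smooth(f)
        assert abs(np.mean([e.x for e in est]) - 100.0) < 0.05

    def test_refit_from_optimum_is_a_fixed_point(self, simulated_kf_fit):
        f = simulated_kf_fit
        f2 = fit(f.track, estimate_psi=True, start=f.params)
        assert f2.neg_loglik == pytest.approx(f.neg_loglik, abs=1e-6)
        assert f2.params.D == pytest.approx(f.params.D, rel=1e-3)

    def test_too_few_observations_rejected(self, rng):
        track = random_small_track(rng, n=4)
        with pytest.raises(ValueError, match="retained"):
            fit(track, min_obs=10)

    def test_standard_errors_reported_on_convergence(self, simulated_kf_fit):
        f = simulated_kf_fit
        assert f.converged
        assert set(f.params_se) == {"D", "psi"}
        assert all(v > 0 for v in f.params_se.values())


@pytest.fixture(scope="module")
def simulated_kf_fit():
    from argosqc import simulate
    cfg = simulate.SimConfig(seed=7, duration_days=6.0, m_shrink=1.3,
                             outlier_rate=0.0)
    _, argos, _ = simulate.simulate_double_tagged(cfg)
    return fit(argos, estimate_psi=True)


class TestPredict:
    def test_interval_longer_than_span_yields_endpoints(self, simulated_kf_fit):
        est = predict(simulated_kf_fit, interval_hours=10_000.0)
        assert len(est) == 2
        sub = simulated_kf_fit.track.retained()
        assert est[0].t == sub.times[0]
        assert est[-1].t == sub.times[-1]

    def test_uncertainty_grows_inside_a_data_gap(self, rng):
        n = 20
        t = np.concatenate([np.arange(10.0), 40.0 + np.arange(10.0)])
        x = np.cumsum(rng.normal(0, 1, n))
        y = np.cumsum(rng.normal(0, 1, n))
        track = make_plane_track(x, y, t, datatype="KF",
                                 smaj=np.full(n, 2.0), smin=np.full(n, 1.0),
                                 eor=np.full(n, 90.0))
        f = fit(track, estimate_psi=False)
        est = predict(f, interval_hours=1.0)
        ses = np.array([e.x_se**2 + e.y_se**2 for e in est])
        th = np.array([(e.t - est[0].t).total_seconds() / 3600.0 for e in est])
        mid_gap = ses[np.argmin(np.abs(th - 25.0))]
        near_obs = ses[np.argmin(np.abs(th - 8.0))]
        assert mid_gap > near_obs

    def test_consistent_with_fitted_states_at_observation_times(self, simulated_kf_fit):
        # one union-grid pass: grid states and observation-time states must
        # coincide exactly wherever a grid time is an observation time
        est, fitted = predict(simulated_kf_fit, interval_hours=2.0,
                              return_fitted=True)
        by_time = {e.t: e for e in est}
        fitted_by_time = {f.t: f for f in fitted}
        shared = [t for t in by_time if t in fitted_by_time]
        assert shared  # the first/last observation times are always on the grid
        for t in shared:
            assert by_time[t].x == pytest.approx(fitted_by_time[t].x, abs=1e-10)
            assert by_time[t].y == pytest.approx(fitted_by_time[t].y, abs=1e-10)

    def test_grid_refinement_shifts_observation_states_only_slightly(self, simulated_kf_fit):
        # the process model is defined on the grid in use, so adding
        # prediction times perturbs observation-time states at the tens-of-
        # metres scale, well under the km-scale measurement uncertainty
        fitted_obs_grid = smooth(simulated_kf_fit)
        _, fitted_union = predict(simulated_kf_fit, interval_hours=2.0,
                                  return_fitted=True)
        d = np.array([np.hypot(a.x - b.x, a.y - b.y)
                      for a, b in zip(fitted_obs_grid, fitted_union)])
        assert d.max() < 0.5  # km

    def test_overfine_grid_rejected(self, simulated_kf_fit):
        with pytest.raises(ValueError, match="finer than 1 s"):
            predict(simulated_kf_fit, interval_hours=1e-5)


class TestStateEstimate:
    def test_confidence_ellipse_axes_from_covariance(self):
        cov = np.diag([4.0, 1.0, 0.1, 0.1])
        e = ssm_core.StateEstimate(t=pd.Timestamp("2020-01-01T00:00Z"),
                                   x=0.0, y=0.0, vx=0.0, vy=0.0, cov=cov)
        chi2_95 = 5.991464547107979
        assert e.ell_major == pytest.approx(np.sqrt(4.0 * chi2_95), rel=1e-6)
        assert e.ell_minor == pytest.approx(np.sqrt(1.0 * chi2_95), rel=1e-6)
        assert e.ell_orient == pytest.approx(90.0)  # long axis east-west
        assert e.x_se == 2.0 and e.y_se == 1.0
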