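"""Independent brute-force oracle for the linear-Gaussian state-space model.

Instead of filtering, the latent states at all observation times are
marginalized explicitly: the joint Gaussian of the stacked state vector is
assembled from the transition matrices and process covariances, the stacked
observation distribution follows by adding the measurement covariances, and
the observation log-density / conditional state moments are computed with
dense linear algebra. Feasible only for tiny tracks, which is the point:
it shares no code path with the Kalman filter or RTS smoother it checks.
"""

import numpy as np

from argosqc.ssm_core import build_transition


def joint_state_moments(t_hours, D, m0, P0):
    """Mean (4n,) and covariance (4n, 4n) of states stacked over times."""
    n = len(t_hours)
    means = [np.asarray(m0, dtype=float)]
    # diag blocks: unconditional Var(s_i); built recursively
    var = [np.asarray(P0, dtype=float)]
    trans = [np.eye(4)]
    for i in range(1, n):
        T, Q = build_transition(t_hours[i] - t_hours[i - 1], D)
        means.append(T @ means[-1])
        var.append(T @ var[-1] @ T.T + Q)
        trans.append(T)
    mu = np.concatenate(means)
    sigma = np.zeros((4 * n, 4 * n))
    for i in range(n):
        sigma[4 * i:4 * i + 4, 4 * i:4 * i + 4] = var[i]
        A = np.eye(4)
        for j in range(i + 1, n):
            A = trans[j] @ A  # A = T_j ... T_{i+1}, mapping s_i -> s_j mean
            block = var[i] @ A.T
            sigma[4 * i:4 * i + 4, 4 * j:4 * j + 4] = block
            sigma[4 * j:4 * j + 4, 4 * i:4 * i + 4] = block.T
    return mu, sigma


def _obs_operator(n):
    H = np.zeros((2 * n, 4 * n))
    for i in range(n):
        H[2 * i, 4 * i] = 1.0      # x
        H[2 * i + 1, 4 * i + 1] = 1.0  # y
    return H


def negloglik_bruteforce(t_hours, obs, omegas, D, m0, P0):
    """-log density of the stacked observations under the joint Gaussian."""
    n = len(t_hours)
    mu, sigma = joint_state_moments(t_hours, D, m0, P0)
    H = _obs_operator(n)
    mean_y = H @ mu
    cov_y = H @ sigma @ H.T
    for i in range(n):
        cov_y[2 * i:2 * i + 2, 2 * i:2 * i + 2] += omegas[i]
    y = np.asarray(obs, dtype=float).ravel()
    r = y - mean_y
    sign, logdet = np.linalg.slogdet(cov_y)
    assert sign > 0
    return 0.5 * (2 * n * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(cov_y, r))


def smooth_bruteforce(t_hours, obs, omegas, D, m0, P0):
    """Conditional mean/cov of every state given all observations.

    Returns (means (n, 4), covs (n, 4, 4)).
    """
    n = len(t_hours)
    mu, sigma = joint_state_moments(t_hours, D, m0, P0)
    H = _obs_operator(n)
    cov_y = H @ sigma @ H.T
    for i in range(n):
        cov_y[2 * i:2 * i + 2, 2 * i:2 * i + 2] += omegas[i]
    y = np.asarray(obs, dtype=float).ravel()
    cross = sigma @ H.T                     # Cov(s, y)
    gain = np.linalg.solve(cov_y, cross.T).T
    mu_post = mu + gain @ (y - H @ mu)
    sigma_post = sigma - gain @ cross.T
    means = mu_post.reshape(n, 4)
    covs = np.array([sigma_post[4 * i:4 * i + 4, 4 * i:4 * i + 4] for i in range(n)])
    return means, covs
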