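"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — explicit matrix inverses, dense
joint-covariance assembly from scratch — and shares no code path with the
implementation it checks.
"""

import numpy as np
from scipy.special import logsumexp

from routegp.gp import matern_kernel
from routegp.model import FlightSet, Hyperparams
from routegp.inference import HyperSamples
from routegp.tracks import beeline


def dense_mvn_loglik(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Gaussian log-density via explicit inverse and determinant."""
    d = x - mean
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return float(
        -0.5 * (d @ np.linalg.inv(cov) @ d + logdet + x.shape[0] * np.log(2 * np.pi))
    )


def dense_condition(mean, cov, n_train, y):
    """Gaussian conditioning with explicit inverse; returns (mean*, cov*)."""
    K_tt = cov[:n_train, :n_train]
    K_qt = cov[n_train:, :n_train]
    K_qq = cov[n_train:, n_train:]
    Kinv = np.linalg.inv(K_tt)
    post_mean = mean[n_train:] + K_qt @ Kinv @ (y - mean[:n_train])
    post_cov = K_qq - K_qt @ Kinv @ K_qt.T
    return post_mean, post_cov


def dense_joint_loglik(flights: FlightSet, h: Hyperparams) -> float:
    """Joint flight-set log-likelihood by assembling the full Sigma densely."""
    ts = [tr.t for tr in flights.trajectories]
    t_all = np.concatenate(ts)
    sigma = matern_kernel(t_all, t_all, h.habitual)
    off = 0
    for t in ts:
        n = t.shape[0]
        sigma[off : off + n, off : off + n] += matern_kernel(t, t, h.flight)
        off += n
    sigma += h.noise_std**2 * np.eye(t_all.shape[0])
    resid = np.concatenate(
        [tr.xy - beeline(flights.site, tr.t) for tr in flights.trajectories]
    )
    return sum(
        dense_mvn_loglik(resid[:, d], np.zeros(t_all.shape[0]), sigma) for d in range(2)
    )


def dense_subset_mig(
    flights: FlightSet, subset_times: np.ndarray, samples: HyperSamples
) -> float:
    """Leave-one-out subset MIG, assembling every joint covariance from scratch."""
    g = flights.t
    n = flights.n_flights
    subset_times = np.atleast_1d(np.asarray(subset_times, dtype=float))
    if subset_times.shape[0] == 0:
        return 0.0
    sub = np.array([int(np.argmin(np.abs(g - t))) for t in subset_times])
    S = len(samples)
    cond = np.zeros((S, n))
    pri = np.zeros((S, n))
    s_grid = beeline(flights.site, g)
    s_sub = beeline(flights.site, g[sub])
    for si, h in enumerate(samples.samples):
        Kqq = (
            matern_kernel(g, g, h.flight)
            + matern_kernel(g, g, h.habitual)
            + h.noise_std**2 * np.eye(g.shape[0])
        )
        for i in range(n):
            others = [j for j in range(n) if j != i]
            m = sub.shape[0]
            nobs = len(others) * m
            # dense covariance of the observation stack [x_j(sub)]_{j != i}
            Kdd = np.tile(matern_kernel(g[sub], g[sub], h.habitual), (len(others), len(others)))
            for b in range(len(others)):
                blk = slice(b * m, (b + 1) * m)
                Kdd[blk, blk] += matern_kernel(g[sub], g[sub], h.flight)
            Kdd += h.noise_std**2 * np.eye(nobs)
            Kqd = np.tile(matern_kernel(g, g[sub], h.habitual), (1, len(others)))
            y = np.stack([flights.trajectories[j].xy[sub] for j in others]).reshape(-1, 2)
            robs = y - np.tile(s_sub, (len(others), 1))
            Kinv = np.linalg.inv(Kdd)
            mean = s_grid + Kqd @ Kinv @ robs
            cov = Kqq - Kqd @ Kinv @ Kqd.T
            xi = flights.trajectories[i].xy
            cond[si, i] = sum(dense_mvn_loglik(xi[:, d], mean[:, d], cov) for d in range(2))
            pri[si, i] = sum(dense_mvn_loglik(xi[:, d], s_grid[:, d], Kqq) for d in range(2))
    per_flight = (logsumexp(cond, axis=0) - np.log(S)) - (logsumexp(pri, axis=0) - np.log(S))
    return float(per_flight.sum())
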