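"""Hierarchical Gaussian-process model of repeated homing flights.

Each observed flight x_i(t) is a noisy GP draw around an unobserved habitual
route h(t), itself a GP centred on the release-to-loft beeline s(t).  With
flight-level kernel k_phi (scales lambda, sigma), route-level kernel k_theta
(scales lambda_h, sigma_h) and isotropic GPS noise of standard deviation eta,
marginalizing h analytically gives a joint Gaussian over all flights with
combined covariance

    Sigma = blockdiag_i[ k_phi(t_i, t_i) ] + k_theta(t_all, t_all) + eta^2 I,

i.e. within-flight blocks k_phi + k_theta + eta^2 I and cross-flight blocks
k_theta alone: flights are coupled only through the shared route.  The two
spatial dimensions (east/north) are modelled as independent GPs sharing one
hyperparameter set, so log-likelihoods add across dimensions.

When all flights live on one common time grid — the package's standard
preprocessing — Sigma is exchangeable across flights, I ⊗ W + J ⊗ K_theta
with W = k_phi + eta^2 I.  An orthogonal contrast transform across the
flight index then block-diagonalizes it into one (W + n K_theta) block and
n-1 copies of W, reducing an (ng)^3 factorization to two g^3 ones.  The
dense path is kept for unequal time vectors and serves as the reference in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .gp import MaternParams, chol_loglik, jittered_cholesky, matern_kernel
from .tracks import SiteGeometry, Trajectory, beeline
from .errors import DomainError, ValidationError

__all__ = [
    "Hyperparams",
    "FlightSet",
    "FlightPrediction",
    "combined_covariance",
    "joint_loglik",
    "flight_loglik_given_route",
    "predict_flight",
    "habitual_route_mean",
]

_HYPER_NAMES = ("lam", "sig", "lam_h", "sig_h", "eta")


@dataclass(frozen=True)
class Hyperparams:
    """Model hyperparameters: flight scales phi, route scales theta, noise eta."""

    flight: MaternParams  # phi = {lambda, sigma}
    habitual: MaternParams  # theta = {lambda_h, sigma_h}
    noise_std: float  # eta, metres

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError(f"noise_std must be >= 0, got {self.noise_std}")

    def to_array(self) -> np.ndarray:
        """(lambda, sigma, lambda_h, sigma_h, eta) as a vector."""
        return np.array(
            [
                self.flight.output_scale,
                self.flight.input_scale,
                self.habitual.output_scale,
                self.habitual.input_scale,
                self.noise_std,
            ]
        )

    @classmethod
    def from_array(cls, values: np.ndarray, order: float = 1.5) -> "Hyperparams":
        lam, sig, lam_h, sig_h, eta = (float(v) for v in values)
        return cls(
            flight=MaternParams(lam, sig, order),
            habitual=MaternParams(lam_h, sig_h, order),
            noise_std=eta,
        )

    names = _HYPER_NAMES


class FlightSet:
    """An ordered set of flights by one bird from one release site."""

    def __init__(self, trajectories: list[Trajectory], site: SiteGeometry):
        if not trajectories:
            raise ValidationError("FlightSet needs at least one trajectory")
        bird_ids = {tr.bird_id for tr in trajectories}
        if len(bird_ids) > 1:
            raise ValidationError(f"FlightSet mixes birds: {sorted(bird_ids)}")
        t0 = trajectories[0].t
        for tr in trajectories[1:]:
            if tr.t.shape != t0.shape or not np.allclose(tr.t, t0, atol=1e-12):
                raise ValidationError("all trajectories must share the common time grid")
        self.trajectories = list(trajectories)
        self.site = site

    @property
    def bird_id(self) -> str:
        return self.trajectories[0].bird_id

    @property
    def t(self) -> np.ndarray:
        """The common time grid."""
        return self.trajectories[0].t

    @property
    def n_flights(self) -> int:
        return len(self.trajectories)

    @property
    def xy(self) -> np.ndarray:
        """Stacked positions, shape (n_flights, grid, 2)."""
        return np.stack([tr.xy for tr in self.trajectories])

    def subset(self, indices: list[int]) -> "FlightSet":
        return FlightSet([self.trajectories[i] for i in indices], self.site)


@dataclass
class FlightPrediction:
    """Predictive distribution for an unseen flight at given query times.

    ``cov`` is the per-dimension predictive covariance; the east and north
    channels share it (isotropic model), so the density of an observed path
    is the sum of two Gaussian log-densities with this covariance.
    """

    query_times: np.ndarray
    mean: np.ndarray  # (n, 2)
    cov: np.ndarray  # (n, n), shared by both spatial dimensions

    def log_density(self, xy: np.ndarray) -> float:
        """log p of an observed path (n, 2) under this prediction."""
        xy = np.asarray(xy, dtype=float)
        if xy.shape != self.mean.shape:
            raise ValueError(f"path shape {xy.shape} != prediction shape {self.mean.shape}")
        L = jittered_cholesky(self.cov)
        return float(np.sum(chol_loglik(L, xy - self.mean)))

    @property
    def marginal_std(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def _kernels(hyper: Hyperparams, t: np.ndarray, u: np.ndarray | None = None):
    u = t if u is None else u
    return matern_kernel(t, u, hyper.flight), matern_kernel(t, u, hyper.habitual)


def combined_covariance(time_vectors: list[np.ndarray], hyper: Hyperparams) -> np.ndarray:
    """The marginalized joint covariance Sigma over concatenated flight times.

    Within-flight block: k_phi + k_theta + eta^2 I; cross-flight block:
    k_theta only (the shared-route coupling).
    """
    if not time_vectors:
        raise ValidationError("need at least one flight time vector")
    ts = [np.atleast_1d(np.asarray(t, dtype=float)) for t in time_vectors]
    for t in ts:
        if np.any(t < 0) or np.any(t > 1):
            raise DomainError("flight times must lie in [0, 1]")
    t_all = np.concatenate(ts)
    sigma = matern_kernel(t_all, t_all, hyper.habitual)
    offset = 0
    for t in ts:
        n = t.shape[0]
        sigma[offset : offset + n, offset : offset + n] += matern_kernel(t, t, hyper.flight)
        offset += n
    sigma[np.diag_indices_from(sigma)] += hyper.noise_std**2
    return sigma


def _common_grid(time_vectors: list[np.ndarray]) -> np.ndarray | None:
    t0 = time_vectors[0]
    for t in time_vectors[1:]:
        if t.shape != t0.shape or not np.array_equal(t, t0):
            return None
    return t0


def joint_loglik(
    flights: FlightSet, hyper: Hyperparams, site: SiteGeometry | None = None
) -> float:
    """Joint log-likelihood of all flights with the habitual route marginalized.

    log N(concat x_i; concat s(t_i), Sigma), summed over the two spatial
    dimensions.  On a common grid the exchangeable fast path is used; the
    result is identical (to numerical precision) to dense evaluation of the
    full Sigma.
    """
    site = flights.site if site is None else site
    ts = [tr.t for tr in flights.trajectories]
    grid = _common_grid(ts)
    if grid is None:
        sigma = combined_covariance(ts, hyper)
        L = jittered_cholesky(sigma)
        resid = np.concatenate(
            [tr.xy - beeline(site, tr.t) for tr in flights.trajectories], axis=0
        )
        return float(np.sum(chol_loglik(L, resid)))

    n = flights.n_flights
    g = grid.shape[0]
    k_phi, k_theta = _kernels(hyper, grid)
    W = k_phi + hyper.noise_std**2 * np.eye(g)
    resid = flights.xy - beeline(site, grid)[None, :, :]  # (n, g, 2)
    mean_sum = resid.sum(axis=0) / np.sqrt(n)  # transformed symmetric component

    L_V = jittered_cholesky(W + n * k_theta)
    ll = float(np.sum(chol_loglik(L_V, mean_sum)))
    if n > 1:
        L_W = jittered_cholesky(W)
        # contrast components: total quadratic form minus the symmetric one,
        # computed without materializing an explicit Helmert basis
        flat = resid.transpose(1, 0, 2).reshape(g, n * 2)
        zW = solve_triangular(L_W, flat, lower=True)
        zW_sym = solve_triangular(L_W, mean_sum, lower=True)
        quad = float(np.sum(zW * zW) - np.sum(zW_sym * zW_sym))
        logdet = 2.0 * np.sum(np.log(np.diag(L_W)))
        ll += -0.5 * quad - (n - 1) * (logdet + g * np.log(2.0 * np.pi))
    return ll


def flight_loglik_given_route(
    traj: Trajectory, route_values: np.ndarray, hyper: Hyperparams
) -> float:
    """log p(x_i | h) for one flight around a known route: N(h(t), k_phi + eta^2 I)."""
    route_values = np.asarray(route_values, dtype=float)
    if route_values.shape != traj.xy.shape:
        raise ValidationError(
            f"route values shape {route_values.shape} does not match flight {traj.xy.shape}"
        )
    g = traj.t.shape[0]
    cov = matern_kernel(traj.t, traj.t, hyper.flight) + hyper.noise_std**2 * np.eye(g)
    L = jittered_cholesky(cov)
    return float(np.sum(chol_loglik(L, traj.xy - route_values)))


def predict_flight(
    observed: FlightSet | None,
    hyper: Hyperparams,
    query_times: np.ndarray,
    site: SiteGeometry,
) -> FlightPrediction:
    """Predictive distribution of an as-yet-unseen flight given observed flights.

    The new flight shares only the route covariance k_theta with the observed
    flights and carries its own flight-level variation and GPS noise, so its
    predictive covariance at the query times is

        k_phi + k_theta + eta^2 I  -  k_theta(q, t_all) Sigma^{-1} k_theta(t_all, q)

    and its mean is the beeline pulled toward the observed flights' shared
    deviations.  With no observed flights the prior itself is returned — by
    symmetry, centred on the beeline.
    """
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    if np.any(q < 0) or np.any(q > 1):
        raise DomainError("query times must lie in [0, 1]")
    k_phi_q, k_theta_q = _kernels(hyper, q)
    prior_cov = k_phi_q + k_theta_q + hyper.noise_std**2 * np.eye(q.shape[0])
    prior_mean = beeline(site, q)
    if observed is None or observed.n_flights == 0:
        return FlightPrediction(query_times=q, mean=prior_mean, cov=prior_cov)

    ts = [tr.t for tr in observed.trajectories]
    t_all = np.concatenate(ts)
    sigma = combined_covariance(ts, hyper)
    K_qD = matern_kernel(q, t_all, hyper.habitual)
    resid = np.concatenate([tr.xy - beeline(site, tr.t) for tr in observed.trajectories])
    L = jittered_cholesky(sigma)
    V = solve_triangular(L, K_qD.T, lower=True)
    alpha = solve_triangular(L, resid, lower=True)
    mean = prior_mean + V.T @ alpha
    cov = prior_cov - V.T @ V
    cov = 0.5 * (cov + cov.T)
    return FlightPrediction(query_times=q, mean=mean, cov=cov)


def habitual_route_mean(
    flights: FlightSet, hyper: Hyperparams, query_times: np.ndarray
) -> np.ndarray:
    """Posterior mean of the habitual route h at the query times, (n, 2).

    The route is never represented explicitly in the likelihood; this
    accessor conditions the k_theta component on all flights (used to place
    identified waypoints in space).  On the common grid the exchangeable
    identity reduces the solve to a single grid-sized system.
    """
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    if np.any(q < 0) or np.any(q > 1):
        raise DomainError("query times must lie in [0, 1]")
    ts = [tr.t for tr in flights.trajectories]
    grid = _common_grid(ts)
    site = flights.site
    if grid is not None:
        n = flights.n_flights
        g = grid.shape[0]
        k_phi, k_theta = _kernels(hyper, grid)
        W = k_phi + hyper.noise_std**2 * np.eye(g)
        resid_sum = (flights.xy - beeline(site, grid)[None, :, :]).sum(axis=0)
        L = jittered_cholesky(W + n * k_theta)
        alpha = solve_triangular(L, resid_sum, lower=True)
        K_qg = matern_kernel(q, grid, hyper.habitual)
        V = solve_triangular(L, K_qg.T, lower=True)
        return beeline(site, q) + V.T @ alpha
    t_all = np.concatenate(ts)
    sigma = combined_covariance(ts, hyper)
    K_qD = matern_kernel(q, t_all, hyper.habitual)
    resid = np.concatenate([tr.xy - beeline(site, tr.t) for tr in flights.trajectories])
    L = jittered_cholesky(sigma)
    V = solve_triangular(L, K_qD.T, lower=True)
    alpha = solve_triangular(L, resid, lower=True)
    return beeline(site, q) + V.T @ alpha
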