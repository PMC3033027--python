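"""Matérn covariance kernels and generic Gaussian-process machinery.

This module is the numerical core shared by the hierarchical flight model:
stationary Matérn kernels (half-integer orders 1/2, 3/2, 5/2), jittered
Cholesky factorization, Gaussian conditioning, and multivariate-normal
log-densities.  Everything downstream funnels its linear algebra through
the helpers here so that the jitter policy is applied uniformly.

Conventions
-----------
The kernel is parameterized as

    k(t, t') = lambda^2 * g_nu(sqrt(2 nu) * |t - t'| / sigma)

where ``lambda`` (output scale, metres) is the standard deviation of the
process at zero lag and ``sigma`` (input scale, normalized-time units) is
the correlation length: k(t, t) = lambda^2 exactly, and k decays
monotonically with |t - t'|.  ``g_nu`` is the standard Matérn-nu
correlation function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import solve_triangular

from .errors import NumericalError

__all__ = [
    "MaternParams",
    "GPSpec",
    "GaussianDist",
    "matern_kernel",
    "jittered_cholesky",
    "chol_loglik",
    "gp_condition",
    "gaussian_loglik",
]

_SUPPORTED_ORDERS = (0.5, 1.5, 2.5)

# Jitter escalation: relative to mean(diag), start small, multiply by 10.
_JITTER_START = 1e-10
_JITTER_MAX = 1e-4


@dataclass(frozen=True)
class MaternParams:
    """Matérn kernel hyperparameters.

    Parameters
    ----------
    output_scale
        lambda, metres.  Standard deviation of the process around its mean.
    input_scale
        sigma, in normalized-time units.  Correlation length; larger values
        give smoother functions (for a trajectory, lower accelerations).
    order
        Matérn smoothness nu, one of {0.5, 1.5, 2.5}.
    """

    output_scale: float
    input_scale: float
    order: float = 1.5

    def __post_init__(self) -> None:
        if not (self.output_scale > 0 and np.isfinite(self.output_scale)):
            raise ValueError(f"output_scale must be positive, got {self.output_scale}")
        if not (self.input_scale > 0 and np.isfinite(self.input_scale)):
            raise ValueError(f"input_scale must be positive, got {self.input_scale}")
        if self.order not in _SUPPORTED_ORDERS:
            raise ValueError(f"order must be one of {_SUPPORTED_ORDERS}, got {self.order}")


@dataclass(frozen=True)
class GPSpec:
    """A Gaussian process: mean function, Matérn kernel, observation noise."""

    mean_fn: Callable[[np.ndarray], np.ndarray]
    kernel: MaternParams
    noise_std: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError(f"noise_std must be >= 0, got {self.noise_std}")

    def prior(self, t: np.ndarray) -> "GaussianDist":
        """Finite-dimensional prior N(m(t), k(t,t) + eta^2 I)."""
        t = np.asarray(t, dtype=float)
        cov = matern_kernel(t, t, self.kernel)
        cov[np.diag_indices_from(cov)] += self.noise_std**2
        return GaussianDist(mean=np.asarray(self.mean_fn(t), dtype=float), cov=cov)


@dataclass
class GaussianDist:
    """A finite multivariate Gaussian with mean vector and covariance matrix."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mean.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError(f"cov shape {self.cov.shape} does not match mean length {n}")
        scale = max(np.abs(self.cov).max(), 1.0)
        if not np.allclose(self.cov, self.cov.T, atol=1e-10 * scale):
            raise ValueError("covariance matrix is not symmetric")
        # enforce exact symmetry so downstream Cholesky sees a clean matrix
        self.cov = 0.5 * (self.cov + self.cov.T)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


def matern_kernel(t: np.ndarray, u: np.ndarray, params: MaternParams) -> np.ndarray:
    """Matérn cross-covariance matrix k(t_i, u_j) for half-integer orders.

    Stationary: entries depend only on |t_i - u_j|.  Zero lag gives exactly
    ``output_scale**2``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    u = np.atleast_1d(np.asarray(u, dtype=float))
    d = np.abs(t[:, None] - u[None, :]) / params.input_scale
    if params.order == 0.5:
        corr = np.exp(-d)
    elif params.order == 1.5:
        a = np.sqrt(3.0) * d
        corr = (1.0 + a) * np.exp(-a)
    else:  # 2.5
        a = np.sqrt(5.0) * d
        corr = (1.0 + a + a * a / 3.0) * np.exp(-a)
    return params.output_scale**2 * corr


def jittered_cholesky(K: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of K, adding relative diagonal jitter on failure.

    Jitter starts at 1e-10 * mean(diag) and escalates tenfold up to
    1e-4 * mean(diag); beyond that a :class:`NumericalError` is raised with a
    condition-number estimate to aid diagnosis.
    """
    K = np.asarray(K, dtype=float)
    scale = float(np.mean(np.diag(K)))
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0
    jitter = 0.0
    while True:
        try:
            return np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))
        except np.linalg.LinAlgError:
            if jitter == 0.0:
                jitter = _JITTER_START * scale
            elif jitter < _JITTER_MAX * scale:
                jitter = min(jitter * 10.0, _JITTER_MAX * scale)
            else:
                cond = float(np.linalg.cond(K))
                raise NumericalError(
                    f"covariance not PSD after jitter escalation to {jitter:.3e} "
                    f"(estimated condition number {cond:.3e})"
                ) from None


def chol_loglik(L: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Gaussian log-density from a precomputed Cholesky factor.

    ``resid`` may be a vector (n,) or a matrix (n, k) of k residual columns;
    returns a scalar or a length-k vector of per-column log-densities.
    """
    n = L.shape[0]
    z = solve_triangular(L, resid, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    quad = np.sum(z * z, axis=0)
    return -0.5 * (quad + logdet + n * np.log(2.0 * np.pi))


def gp_condition(prior: GaussianDist, train_values: np.ndarray) -> GaussianDist:
    """Condition a joint Gaussian over [train ∪ query] points on train values.

    The first ``len(train_values)`` coordinates of ``prior`` are the training
    block; the remainder is the query block.  Returns the posterior Gaussian
    over the query block:

        mean*  = m_q + K_qt K_tt^{-1} (y - m_t)
        cov*   = K_qq - K_qt K_tt^{-1} K_tq

    With zero training points the prior is returned unchanged.
    """
    y = np.asarray(train_values, dtype=float)
    n_train = y.shape[0]
    if n_train == 0:
        return GaussianDist(mean=prior.mean.copy(), cov=prior.cov.copy())
    if n_train > prior.dim:
        raise ValueError(f"{n_train} training values exceed prior dimension {prior.dim}")
    K_tt = prior.cov[:n_train, :n_train]
    K_qt = prior.cov[n_train:, :n_train]
    K_qq = prior.cov[n_train:, n_train:]
    L = jittered_cholesky(K_tt)
    # V = L^{-1} K_tq  so that  K_qt K_tt^{-1} K_tq = V^T V
    V = solve_triangular(L, K_qt.T, lower=True)
    alpha = solve_triangular(L, y - prior.mean[:n_train], lower=True)
    post_mean = prior.mean[n_train:] + V.T @ alpha
    post_cov = K_qq - V.T @ V
    post_cov = 0.5 * (post_cov + post_cov.T)
    return GaussianDist(mean=post_mean, cov=post_cov)


def gaussian_loglik(x: np.ndarray, dist: GaussianDist) -> float:
    """log N(x; dist.mean, dist.cov) via jittered Cholesky."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != dist.dim:
        raise ValueError(f"x has length {x.shape[0]}, distribution has dimension {dist.dim}")
    L = jittered_cholesky(dist.cov)
    return float(chol_loglik(L, x - dist.mean))
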