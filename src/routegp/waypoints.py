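"""Greedy identification of navigational waypoints with Bayes-factor stopping.

A waypoint is a normalized time t (and the corresponding point on the
habitual route) whose observations across past flights are maximally
informative about the remaining flights.  The selection objective is the
summed leave-one-out marginal information gain of a candidate subset t^m:

    MIG(t^m) = sum_i [ log p(x_i | {x_{\\i}(t^m)}, M) - log p(x_i | M) ],

the sum over flights damping the influence of any single outlier flight.
Hyperparameters are marginalized under the *prior* during selection: the
algorithm must capture spatial information, not pick clustered points that
merely pin down the kernel scales (a posterior-marginalized variant is
available as a robustness check).

Selection is greedy forward: at each step the candidate with the largest
MIG gain is chosen among the N grid candidates.  Whether to keep it is a
Bayes-factor model comparison between the current waypoint set (M0) and the
set plus one additional waypoint whose position is marginalized uniformly
over the N candidates (M1):

    log BF = log [ (1/N) * sum_j exp(Delta_j) ],    Delta_j = MIG gain of candidate j.

Marginalizing the new waypoint's position is the Occam penalty: a waypoint
is only accepted when gains are large over enough of the candidate grid to
outweigh the many candidates that add nothing.  Selection stops at the
first log BF below zero.

Because every flight lives on one common grid, the leave-one-out
conditionals have exchangeable structure across flights, and each candidate
evaluation reduces to one m x m solve plus one grid-sized factorization
shared by all flights (see ``_SelectionEngine``).  The dense construction
survives as the brute-force oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp, softmax

from .errors import ValidationError
from .gp import chol_loglik, jittered_cholesky, matern_kernel
from .inference import HyperPrior, HyperSamples, mh_sample, prior_samples
from .model import FlightSet, habitual_route_mean, joint_loglik
from .tracks import SiteGeometry, beeline, inverse_project

__all__ = [
    "CandidateGrid",
    "SelectionStep",
    "WaypointSet",
    "subset_mig",
    "greedy_step",
    "identify_waypoints",
    "waypoint_report",
]


@dataclass(frozen=True)
class CandidateGrid:
    """The N candidate waypoint times (by default the common resampling grid)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if np.any(np.diff(times) <= 0) or times[0] < 0 or times[-1] > 1:
            raise ValidationError("candidate times must be sorted, distinct, within [0, 1]")
        object.__setattr__(self, "times", times)

    @property
    def n(self) -> int:
        return self.times.shape[0]


@dataclass(frozen=True)
class SelectionStep:
    """One greedy iteration: the best candidate and the accept/reject evidence."""

    chosen_time: float
    summed_mig: float  # selection objective with the chosen candidate included
    log_bf: float  # log Bayes factor for adding one position-marginalized waypoint
    accepted: bool


@dataclass
class WaypointSet:
    """Result of waypoint identification for one bird."""

    bird_id: str
    selected_times: np.ndarray  # in selection order
    locations: np.ndarray  # (k, 2) habitual-route posterior mean, metres
    trace: list[SelectionStep]

    @property
    def n_waypoints(self) -> int:
        return self.selected_times.shape[0]


def _grid_indices(times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(grid, times)
    idx = np.clip(idx, 0, grid.shape[0] - 1)
    left = np.clip(idx - 1, 0, None)
    idx = np.where(np.abs(grid[left] - times) < np.abs(grid[idx] - times), left, idx)
    if np.any(np.abs(grid[idx] - times) > 1e-9):
        raise ValidationError("subset times must lie on the candidate grid")
    return idx


class _SelectionEngine:
    """Caches per-hyperparameter-sample kernels for fast repeated subset scoring.

    For the leave-one-out conditional of flight i given the other flights'
    observations at subset indices ``sub`` (size m, n_o = n-1 observed
    flights), the exchangeable structure gives, with A = k_theta(grid, sub),
    B = (k_phi + k_theta + eta^2 I)[sub, sub], C = k_theta[sub, sub] and
    D = B + (n_o - 1) C:

        cov_i  = prior_cov - n_o * A D^{-1} A^T           (same for all i)
        mean_i = s(grid) + A D^{-1} sum_{j != i} r_j(sub)

    so one m x m factorization and one grid-sized factorization serve every
    flight and both spatial dimensions.
    """

    def __init__(self, flights: FlightSet, hyper_samples: HyperSamples):
        if flights.n_flights < 2:
            raise ValidationError("waypoint selection needs at least 2 flights")
        self.flights = flights
        self.samples = hyper_samples
        grid = flights.t
        g = grid.shape[0]
        n = flights.n_flights
        self.grid = grid
        self.resid = flights.xy - beeline(flights.site, grid)[None, :, :]  # (n, g, 2)
        self._resid_flat = self.resid.transpose(1, 0, 2).reshape(g, n * 2)

        self._k_phi: list[np.ndarray] = []
        self._k_theta: list[np.ndarray] = []
        self._eta2: list[float] = []
        self._prior_cov: list[np.ndarray] = []
        prior_ll = []
        for h in hyper_samples.samples:
            k_phi = matern_kernel(grid, grid, h.flight)
            k_theta = matern_kernel(grid, grid, h.habitual)
            eta2 = h.noise_std**2
            prior_cov = k_phi + k_theta + eta2 * np.eye(g)
            Lp = jittered_cholesky(prior_cov)
            prior_ll.append(chol_loglik(Lp, self._resid_flat).reshape(n, 2).sum(axis=1))
            self._k_phi.append(k_phi)
            self._k_theta.append(k_theta)
            self._eta2.append(eta2)
            self._prior_cov.append(prior_cov)
        self.prior_ll = np.stack(prior_ll)  # (S, n)

    def cond_loglik(self, sub: np.ndarray) -> np.ndarray:
        """(S, n) log p(x_i(grid) | other flights at subset), per hyper sample."""
        n = self.flights.n_flights
        g = self.grid.shape[0]
        m = sub.shape[0]
        n_o = n - 1
        out = np.empty((len(self.samples), n))
        sub_ix = np.ix_(sub, sub)
        r_sub = self.resid[:, sub, :]  # (n, m, 2)
        total = r_sub.sum(axis=0)  # (m, 2)
        # w_i = sum_{j != i} r_j(sub), flattened to (m, n*2)
        w = (total[None, :, :] - r_sub).transpose(1, 0, 2).reshape(m, n * 2)
        for s in range(len(self.samples)):
            k_theta = self._k_theta[s]
            A = k_theta[:, sub]  # (g, m)
            C = k_theta[sub_ix]
            B = self._k_phi[s][sub_ix] + C + self._eta2[s] * np.eye(m)
            D = B + (n_o - 1) * C
            LD = jittered_cholesky(D)
            X = solve_triangular(LD, A.T, lower=True)  # (m, g)
            post_cov = self._prior_cov[s] - n_o * (X.T @ X)
            Lc = jittered_cholesky(0.5 * (post_cov + post_cov.T))
            z = solve_triangular(LD, w, lower=True)
            Dinv_w = solve_triangular(LD.T, z, lower=False)
            resid = self._resid_flat - A @ Dinv_w  # (g, n*2)
            out[s] = chol_loglik(Lc, resid).reshape(n, 2).sum(axis=1)
        return out

    def objective(self, sub: np.ndarray) -> float:
        """Summed leave-one-out MIG of the subset (empty subset scores 0)."""
        if sub.shape[0] == 0:
            return 0.0
        cond = self.cond_loglik(sub)
        S = cond.shape[0]
        per_flight = (logsumexp(cond, axis=0) - np.log(S)) - (
            logsumexp(self.prior_ll, axis=0) - np.log(S)
        )
        return float(per_flight.sum())


def subset_mig(
    flights: FlightSet,
    subset_times: np.ndarray,
    hyper_samples: HyperSamples,
    site: SiteGeometry | None = None,
) -> float:
    """Summed leave-one-out MIG of observing each flight at ``subset_times``.

    Each flight's full-grid trajectory is predicted from the *other* flights'
    observations at the subset times; gains are hyperparameter-marginalized
    and summed over flights.  The empty subset scores exactly zero.
    """
    del site  # geometry travels with the FlightSet
    subset_times = np.atleast_1d(np.asarray(subset_times, dtype=float))
    if subset_times.shape[0] == 0:
        return 0.0
    engine = _SelectionEngine(flights, hyper_samples)
    return engine.objective(_grid_indices(subset_times, flights.t))


def greedy_step(
    flights: FlightSet,
    selected: np.ndarray,
    grid: CandidateGrid,
    hyper_samples: HyperSamples,
    site: SiteGeometry | None = None,
    _engine: _SelectionEngine | None = None,
) -> SelectionStep:
    """One greedy iteration: score every unselected candidate, pick the best.

    Returns the chosen time (ties broken toward the earliest time), the
    objective value with it included, and the log Bayes factor for adding a
    position-marginalized waypoint; ``accepted`` is ``log_bf > 0``.
    """
    del site
    engine = _engine if _engine is not None else _SelectionEngine(flights, hyper_samples)
    selected = np.atleast_1d(np.asarray(selected, dtype=float))
    sel_idx = _grid_indices(selected, engine.grid) if selected.shape[0] else np.array([], int)
    cand_idx = _grid_indices(grid.times, engine.grid)
    unselected = np.array([j for j in cand_idx if j not in set(sel_idx.tolist())])
    if unselected.shape[0] == 0:
        raise ValidationError("all candidates already selected")

    base = engine.objective(sel_idx)
    deltas = np.empty(unselected.shape[0])
    for k, j in enumerate(unselected):
        trial = np.concatenate([sel_idx, [j]]).astype(int)
        deltas[k] = engine.objective(trial) - base
    best = int(np.argmax(deltas))  # first max: earliest time wins ties
    log_bf = float(logsumexp(deltas) - np.log(grid.n))
    return SelectionStep(
        chosen_time=float(engine.grid[unselected[best]]),
        summed_mig=base + float(deltas[best]),
        log_bf=log_bf,
        accepted=log_bf > 0,
    )


def identify_waypoints(
    flights: FlightSet,
    prior: HyperPrior,
    n_hyper_samples: int = 1000,
    seed: int = 0,
    grid: CandidateGrid | None = None,
    use_posterior: bool = False,
    mh_burn_in: int = 500,
) -> WaypointSet:
    """Full greedy waypoint identification for one bird's flight set.

    Hyperparameter samples are drawn once — from the prior by default, or
    from the MH posterior given all flights when ``use_posterior`` is set
    (the robustness-check variant) — then greedy steps run until the first
    rejected step or candidate exhaustion.  The rejected step is recorded in
    the trace but its candidate is not retained.  Waypoint locations are the
    posterior mean of the habitual route at the selected times, with
    hyperparameters importance-weighted by each sample's joint likelihood.
    """
    if grid is None:
        grid = CandidateGrid(flights.t)
    if use_posterior:
        samples = mh_sample(
            flights, prior, n_samples=n_hyper_samples, seed=seed, burn_in=mh_burn_in
        )
    else:
        samples = prior_samples(prior, n_hyper_samples, seed=seed)
    engine = _SelectionEngine(flights, samples)

    selected: list[float] = []
    trace: list[SelectionStep] = []
    n_candidates = grid.n
    while len(selected) < n_candidates:
        step = greedy_step(flights, np.array(selected), grid, samples, _engine=engine)
        trace.append(step)
        if not step.accepted:
            break
        selected.append(step.chosen_time)

    times = np.array(selected)
    if times.shape[0]:
        loglik = np.array([joint_loglik(flights, h) for h in samples.samples])
        weights = softmax(loglik)
        locations = np.zeros((times.shape[0], 2))
        for w, h in zip(weights, samples.samples):
            if w > 0:
                locations += w * habitual_route_mean(flights, h, times)
    else:
        locations = np.zeros((0, 2))
    return WaypointSet(
        bird_id=flights.bird_id, selected_times=times, locations=locations, trace=trace
    )


def waypoint_report(ws: WaypointSet, origin: tuple[float, float]) -> pd.DataFrame:
    """Geographic waypoint table in selection order.

    Columns: order, t, east_m, north_m, lat, lon, delta_mig (the MIG gain of
    that step) and log_bf.  Locations are inverse-projected about ``origin``.
    """
    columns = ["order", "t", "east_m", "north_m", "lat", "lon", "delta_mig", "log_bf"]
    accepted = [s for s in ws.trace if s.accepted]
    rows = []
    prev = 0.0
    for order, (step, loc) in enumerate(zip(accepted, ws.locations), start=1):
        latlon = inverse_project(loc, origin)[0]
        rows.append(
            {
                "order": order,
                "t": step.chosen_time,
                "east_m": loc[0],
                "north_m": loc[1],
                "lat": latlon[0],
                "lon": latlon[1],
                "delta_mig": step.summed_mig - prev,
                "log_bf": step.log_bf,
            }
        )
        prev = step.summed_mig
    return pd.DataFrame(rows, columns=columns)
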