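"""Marginal information gain: how predictable is a flight from its predecessors?

MIG of flight i is the log-ratio of its probability conditioned on the two
most recent flights to its prior probability,

    MIG_i = log p(x_i | x_{i-1}, x_{i-2}, M) - log p(x_i | M),

with hyperparameters numerically marginalized in both terms.  Positive MIG
means the flight is more likely in the light of its predecessors than a
priori — predictable, route-following behaviour; negative MIG means the
flights are more probable as independent draws, i.e. no habitual route.
Units are nats.

For the learning curve across a training series, hyperparameters are re-fit
(MH posterior) to each prediction's two conditioning flights — the smallest
honest information set, mirroring a prequential design — and the per-flight
MIG is aggregated across birds as a median with interquartile range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import HyperPrior, HyperSamples, marginal_loglik, mh_sample
from .model import FlightSet, predict_flight
from .tracks import SiteGeometry, Trajectory

__all__ = ["MIGResult", "MIGCurve", "mig", "mig_curve"]


@dataclass(frozen=True)
class MIGResult:
    """MIG of one predicted flight, with the number of conditioning flights used."""

    flight_number: int
    mig: float  # nats; total over the whole trajectory
    n_conditioning: int
    bird_id: str = ""


@dataclass
class MIGCurve:
    """Per-flight MIG across birds plus a median/IQ-range summary per flight number."""

    results: list[MIGResult]
    summary: pd.DataFrame  # columns: flight, median, iq_lo, iq_hi, n_birds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "bird_id": r.bird_id,
                    "flight": r.flight_number,
                    "mig_nats": r.mig,
                    "n_conditioning": r.n_conditioning,
                }
                for r in self.results
            ]
        )


def mig(
    flight: Trajectory,
    predecessors: list[Trajectory],
    hyper_samples: HyperSamples,
    site: SiteGeometry,
    per_point: bool = False,
) -> MIGResult:
    """MIG of one flight given up to two predecessor flights.

    Both the conditional and the prior term are marginalized over
    ``hyper_samples`` by log-mean-exp; with no predecessors the two terms
    coincide and MIG is exactly zero.  ``per_point=True`` divides by the
    number of grid points (a density useful for comparing grids; the default
    total matches whole-trajectory probabilities).
    """
    if len(predecessors) > 2:
        predecessors = predecessors[-2:]
    if len(hyper_samples) == 0:
        raise ValueError("hyper_samples must be non-empty")
    if not predecessors:
        return MIGResult(flight.flight_number, 0.0, 0, flight.bird_id)

    observed = FlightSet(predecessors, site)

    def conditional(h):
        return predict_flight(observed, h, flight.t, site).log_density(flight.xy)

    def prior_term(h):
        return predict_flight(None, h, flight.t, site).log_density(flight.xy)

    value = marginal_loglik(conditional, hyper_samples) - marginal_loglik(
        prior_term, hyper_samples
    )
    if per_point:
        value /= flight.t.shape[0]
    return MIGResult(flight.flight_number, float(value), len(predecessors), flight.bird_id)


def mig_curve(
    birds: list[FlightSet],
    prior: HyperPrior,
    seed: int = 0,
    n_samples: int = 1000,
    burn_in: int = 500,
) -> MIGCurve:
    """MIG learning curve across birds.

    For each bird with at least three flights, every flight with at least one
    predecessor is predicted from its (up to two) immediate predecessors,
    with hyperparameters sampled from the posterior given those conditioning
    flights.  Birds with fewer than three flights are skipped with a warning.
    """
    root = np.random.SeedSequence(seed)
    results: list[MIGResult] = []
    for bird, bird_seq in zip(birds, root.spawn(len(birds))):
        if bird.n_flights < 3:
            warnings.warn(
                f"bird {bird.bird_id}: only {bird.n_flights} flights, skipped "
                "(need >= 3 for a learning curve)",
                stacklevel=2,
            )
            continue
        flight_seeds = bird_seq.generate_state(bird.n_flights)
        for i in range(1, bird.n_flights):
            preds = bird.trajectories[max(0, i - 2) : i]
            samples = mh_sample(
                FlightSet(preds, bird.site),
                prior,
                n_samples=n_samples,
                seed=int(flight_seeds[i] % (2**31)),
                burn_in=burn_in,
                site=bird.site,
            )
            results.append(mig(bird.trajectories[i], preds, samples, bird.site))

    rows = []
    by_flight: dict[int, list[float]] = {}
    for r in results:
        by_flight.setdefault(r.flight_number, []).append(r.mig)
    for flight_number in sorted(by_flight):
        vals = np.array(by_flight[flight_number])
        rows.append(
            {
                "flight": flight_number,
                "median": float(np.median(vals)),
                "iq_lo": float(np.percentile(vals, 25)),
                "iq_hi": float(np.percentile(vals, 75)),
                "n_birds": vals.shape[0],
            }
        )
    summary = pd.DataFrame(rows, columns=["flight", "median", "iq_lo", "iq_hi", "n_birds"])
    return MIGCurve(results=results, summary=summary)
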