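"""Generative simulator of habitual-route flight ensembles.

Emulates a training series of homing flights: a smooth habitual route
deviating from the release-to-loft beeline, repeated flights varying
smoothly and independently around that route, and isotropic GPS noise.
Default scales mirror a typical training study: a ~5 km beeline, 20
releases, a 100-point grid and 5 m GPS noise.

Route modes
-----------
``gp_draw``
    One draw of h ~ GP(s(t), k_theta) shared by all flights — the model's
    own generative assumption, used for calibration checks.
``piecewise``
    The beeline plus localized smooth perpendicular detours peaking exactly
    at given turn times.  GP-drawn routes have no discrete ground truth;
    piecewise routes provide unambiguous turn points for recovery tests.
``beeline``
    No route deviation at all — the null against which the Occam behaviour
    of the selection algorithm is checked.
``independent_routes``
    A fresh GP route per flight: flights share nothing, the no-habitual-
    route null for the MIG sign tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .gp import MaternParams, jittered_cholesky, matern_kernel
from .model import FlightSet, Hyperparams
from .tracks import (
    RawTrack,
    SiteGeometry,
    Trajectory,
    beeline,
    inverse_project,
    write_tracks_csv,
    write_tracks_gpx,
)

__all__ = ["SimConfig", "default_site", "default_hyper", "sample_habitual_route", "sample_flights", "export_fixture"]

_ROUTE_MODES = ("gp_draw", "piecewise", "beeline", "independent_routes")


def default_site() -> SiteGeometry:
    """A 5 km release-to-loft geometry with the loft at the projection origin."""
    return SiteGeometry(
        release=np.array([-3000.0, 4000.0]),
        loft=np.array([0.0, 0.0]),
        projection_origin=(51.78, -1.31),
    )


def default_hyper() -> Hyperparams:
    """Realistic flight-scale defaults for a ~5 km homing flight.

    Flight-to-flight variation 150 m with correlation length 0.25 of the
    flight; habitual-route deviation 500 m (10% of the beeline) with
    correlation length 0.2; GPS noise 5 m.
    """
    return Hyperparams(
        flight=MaternParams(150.0, 0.25),
        habitual=MaternParams(500.0, 0.2),
        noise_std=5.0,
    )


@dataclass(frozen=True)
class SimConfig:
    """Settings for one simulated flight ensemble."""

    site: SiteGeometry = field(default_factory=default_site)
    hyper: Hyperparams = field(default_factory=default_hyper)
    n_flights: int = 20
    grid_size: int = 100
    seed: int = 0
    route_mode: str = "gp_draw"
    turn_times: tuple[float, ...] = ()
    turn_offsets: tuple[float, ...] = ()  # metres, perpendicular to the beeline
    turn_halfwidth: float = 0.1  # normalized-time width of each detour's profile
    bird_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n_flights < 1:
            raise ValidationError("n_flights must be >= 1")
        if self.grid_size < 2:
            raise ValidationError("grid_size must be >= 2")
        if self.route_mode not in _ROUTE_MODES:
            raise ValidationError(f"route_mode must be one of {_ROUTE_MODES}")
        tt = np.asarray(self.turn_times, dtype=float)
        if self.route_mode == "piecewise":
            if tt.shape[0] == 0 or len(self.turn_offsets) != tt.shape[0]:
                raise ValidationError("piecewise mode needs matching turn_times and turn_offsets")
            if np.any(tt <= 0) or np.any(tt >= 1) or np.any(np.diff(tt) <= 0):
                raise ValidationError("turn_times must be strictly increasing within (0, 1)")
            if self.turn_halfwidth <= 0:
                raise ValidationError("turn_halfwidth must be positive")
            if np.any(np.diff(tt) < 2 * self.turn_halfwidth):
                raise ValidationError("turn_times closer than 2 * turn_halfwidth would overlap")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.grid_size)


def _perpendicular(site: SiteGeometry) -> np.ndarray:
    d = site.loft - site.release
    d = d / np.linalg.norm(d)
    return np.array([-d[1], d[0]])


def _gp_route_factor(cfg: SimConfig) -> np.ndarray:
    cov = matern_kernel(cfg.grid, cfg.grid, cfg.hyper.habitual)
    return jittered_cholesky(cov)


def sample_habitual_route(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """One habitual route on the grid, (grid_size, 2) metres.

    ``gp_draw`` uses (and consumes) ``rng``; the deterministic modes ignore it.
    """
    t = cfg.grid
    base = beeline(cfg.site, t)
    if cfg.route_mode == "beeline":
        return base
    if cfg.route_mode == "piecewise":
        # localized smooth bumps peaking exactly at the turn times: the route
        # detours perpendicular to the beeline with a Gaussian profile of
        # width turn_halfwidth and returns to the beeline in between, so the
        # apexes are the only ground-truth structure points
        w = cfg.turn_halfwidth
        offset = np.zeros_like(t)
        for tk, off in zip(cfg.turn_times, cfg.turn_offsets):
            offset += off * np.exp(-0.5 * ((t - tk) / w) ** 2)
        # detrend so the route passes exactly through release and loft
        offset -= (1.0 - t) * offset[0] + t * offset[-1]
        return base + offset[:, None] * _perpendicular(cfg.site)[None, :]
    # gp_draw (also used per-flight by independent_routes)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = _gp_route_factor(cfg)
    return base + L @ rng.standard_normal((cfg.grid_size, 2))


def sample_flights(cfg: SimConfig) -> FlightSet:
    """A seeded ensemble of flights around the configured habitual route.

    Each flight is route + GP(0, k_phi) deviation + N(0, eta^2) noise per
    spatial dimension.  In ``independent_routes`` mode every flight draws its
    own route — the flights then share nothing beyond the beeline.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.grid
    g = cfg.grid_size
    n = cfg.n_flights
    L_phi = jittered_cholesky(matern_kernel(t, t, cfg.hyper.flight))

    if cfg.route_mode == "independent_routes":
        L_theta = _gp_route_factor(cfg)
        base = beeline(cfg.site, t)
        routes = base[None, :, :] + np.einsum(
            "ij,njd->nid", L_theta, rng.standard_normal((n, g, 2))
        )
    else:
        route = sample_habitual_route(cfg, rng)
        routes = np.broadcast_to(route, (n, g, 2))

    deviations = np.einsum("ij,njd->nid", L_phi, rng.standard_normal((n, g, 2)))
    noise = cfg.hyper.noise_std * rng.standard_normal((n, g, 2))
    xy = routes + deviations + noise
    trajectories = [
        Trajectory(bird_id=cfg.bird_id, flight_number=i + 1, t=t.copy(), xy=xy[i])
        for i in range(n)
    ]
    return FlightSet(trajectories, cfg.site)


_EPOCH = 1230768000.0  # 2009-01-01T00:00:00Z; fixtures are timestamped at 1 Hz from here


def export_fixture(
    fs: FlightSet,
    path: str | Path,
    origin: tuple[float, float] | None = None,
    format: str = "csv",
) -> list[RawTrack]:
    """Write a flight set as raw GPS tracks so the full pipeline can re-ingest it.

    Positions are inverse-projected to lat/lon about ``origin`` (default: the
    site's projection origin) and timestamped at 1 Hz, one grid point per
    second.  Returns the written tracks.
    """
    if fs.n_flights == 0:
        raise ValidationError("cannot export an empty FlightSet")
    origin = fs.site.projection_origin if origin is None else origin
    tracks = []
    for k, tr in enumerate(fs.trajectories):
        latlon = inverse_project(tr.xy, origin)
        n = tr.t.shape[0]
        t0 = _EPOCH + k * 86400.0  # one release per day
        tracks.append(
            RawTrack(
                bird_id=tr.bird_id,
                flight_number=tr.flight_number,
                t=t0 + np.arange(n, dtype=float),
                lat=latlon[:, 0],
                lon=latlon[:, 1],
            )
        )
    if format == "csv":
        write_tracks_csv(tracks, path)
    elif format == "gpx":
        write_tracks_gpx(tracks, path)
    else:
        raise ValueError(f"unknown fixture format {format!r}")
    return tracks


def write_truth(cfg: SimConfig, path: str | Path) -> None:
    """Ground-truth JSON next to a fixture: route mode, turns, hyperparameters, seed."""
    payload = {
        "seed": cfg.seed,
        "route_mode": cfg.route_mode,
        "turn_times": list(cfg.turn_times),
        "turn_offsets_m": list(cfg.turn_offsets),
        "n_flights": cfg.n_flights,
        "grid_size": cfg.grid_size,
        "hyperparams": dict(zip(Hyperparams.names, cfg.hyper.to_array().tolist())),
        "release_m": cfg.site.release.tolist(),
        "loft_m": cfg.site.loft.tolist(),
        "projection_origin": list(cfg.site.projection_origin),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
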