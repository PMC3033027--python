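"""Reading, projecting, cleaning and time-normalizing GPS tracks.

Raw GPS tracks (CSV or GPX 1.1) are turned into model-ready trajectories:
planar coordinates in metres about a reference origin, with time mapped to
a proportion of total flight duration on a common uniform grid.  Pipeline:

    read_tracks -> project_to_plane -> remove_stationary -> normalize_and_resample

The projection is a local equirectangular map about a configurable origin
(by default the home loft): east = R cos(lat0) dlon, north = R dlat with
R = 6 371 000 m.  Over the < 20 km spans of a homing flight its distortion
is far below GPS noise, which is why no geodesy library is pulled in.

CSV dialect: header ``bird_id,flight,timestamp,lat,lon``; timestamps are
ISO-8601 strings or plain numeric seconds.  GPX dialect: one ``<trk>`` per
flight, bird id in ``<name>``, flight number in ``<number>``.
"""

from __future__ import annotations

import csv
import datetime as _dt
import math
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .errors import DegenerateTrackError, DomainError, ParseError, ValidationError

__all__ = [
    "RawTrack",
    "PlanarTrack",
    "Trajectory",
    "SiteGeometry",
    "EARTH_RADIUS_M",
    "read_tracks",
    "write_tracks_csv",
    "write_tracks_gpx",
    "write_trajectories_csv",
    "project_to_plane",
    "inverse_project",
    "remove_stationary",
    "normalize_and_resample",
    "beeline",
]

EARTH_RADIUS_M = 6_371_000.0

_CSV_HEADER = ["bird_id", "flight", "timestamp", "lat", "lon"]
_GPX_NS = "http://www.topografix.com/GPX/1/1"


@dataclass
class RawTrack:
    """One recorded flight: (timestamp, lat, lon) samples sorted by time."""

    bird_id: str
    flight_number: int
    t: np.ndarray  # seconds since epoch
    lat: np.ndarray  # degrees
    lon: np.ndarray  # degrees

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.flight_number < 1:
            raise ValidationError(f"flight_number must be >= 1, got {self.flight_number}")
        if self.t.shape[0] < 2:
            raise ValidationError(f"track {self.bird_id}/{self.flight_number} has < 2 samples")
        if not (self.t.shape == self.lat.shape == self.lon.shape):
            raise ValidationError("t, lat, lon must have equal lengths")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"track {self.bird_id}/{self.flight_number}: timestamps not strictly increasing"
            )
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValidationError(
                f"track {self.bird_id}/{self.flight_number}: lat/lon out of range"
            )

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]


@dataclass
class PlanarTrack:
    """A track after projection: time in seconds, planar xy in metres."""

    bird_id: str
    flight_number: int
    t: np.ndarray  # seconds (monotone increasing)
    xy: np.ndarray  # (n, 2) metres east/north of the projection origin


@dataclass
class Trajectory:
    """A model-ready flight: normalized times in [0, 1] and planar positions."""

    bird_id: str
    flight_number: int
    t: np.ndarray  # normalized times, t[0] = 0, t[-1] = 1
    xy: np.ndarray  # (n, 2) metres

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (self.t.shape[0], 2):
            raise ValidationError("t must be (n,) and xy (n, 2)")
        if self.t[0] != 0.0 or self.t[-1] != 1.0 or np.any(np.diff(self.t) <= 0):
            raise ValidationError("t must be sorted with t[0]=0 and t[-1]=1")
        if not np.all(np.isfinite(self.xy)):
            raise ValidationError("positions must be finite")


@dataclass
class SiteGeometry:
    """Release point and home loft in planar coordinates, plus projection origin."""

    release: np.ndarray  # (2,) metres
    loft: np.ndarray  # (2,) metres
    projection_origin: tuple[float, float]  # (lat, lon) degrees

    def __post_init__(self) -> None:
        self.release = np.asarray(self.release, dtype=float)
        self.loft = np.asarray(self.loft, dtype=float)
        if np.allclose(self.release, self.loft):
            raise ValidationError("release and loft must differ")

    @property
    def beeline_length(self) -> float:
        return float(np.linalg.norm(self.loft - self.release))


# ---------------------------------------------------------------------------
# reading / writing


def _parse_timestamp(text: str, path: str, line_no: int) -> float:
    text = text.strip()
    try:
        return float(text)
    except ValueError:
        pass
    try:
        ts = text.replace("Z", "+00:00")
        dt = _dt.datetime.fromisoformat(ts)
        if dt.tzinfo is None:
            dt = dt.replace(tzinfo=_dt.timezone.utc)
        return dt.timestamp()
    except ValueError:
        raise ParseError(f"{path}:{line_no}: cannot parse timestamp {text!r}") from None


def _finish_tracks(rows: dict) -> list[RawTrack]:
    tracks = []
    for (bird, flight), (ts, lats, lons) in sorted(rows.items()):
        order = np.argsort(ts, kind="stable")
        t = np.asarray(ts, dtype=float)[order]
        if np.any(np.diff(t) == 0):
            raise ValidationError(f"track {bird}/{flight}: duplicate timestamps")
        tracks.append(
            RawTrack(
                bird_id=bird,
                flight_number=flight,
                t=t,
                lat=np.asarray(lats, dtype=float)[order],
                lon=np.asarray(lons, dtype=float)[order],
            )
        )
    return tracks


def _read_csv(path: Path) -> list[RawTrack]:
    rows: dict = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}:1: empty file") from None
        if [h.strip().lower() for h in header] != _CSV_HEADER:
            raise ParseError(f"{path}:1: expected header {','.join(_CSV_HEADER)}")
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ParseError(f"{path}:{line_no}: expected 5 columns, got {len(row)}")
            bird, flight_s, ts_s, lat_s, lon_s = (c.strip() for c in row)
            try:
                flight = int(flight_s)
                lat = float(lat_s)
                lon = float(lon_s)
            except ValueError:
                raise ParseError(f"{path}:{line_no}: malformed numeric field") from None
            ts = _parse_timestamp(ts_s, str(path), line_no)
            rows.setdefault((bird, flight), ([], [], []))
            rows[(bird, flight)][0].append(ts)
            rows[(bird, flight)][1].append(lat)
            rows[(bird, flight)][2].append(lon)
    return _finish_tracks(rows)


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_gpx(path: Path) -> list[RawTrack]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from None
    rows: dict = {}
    trk_idx = 0
    for trk in root.iter():
        if _strip_ns(trk.tag) != "trk":
            continue
        trk_idx += 1
        bird = f"track{trk_idx}"
        flight = trk_idx
        ts_list: list[float] = []
        lat_list: list[float] = []
        lon_list: list[float] = []
        for child in trk:
            tag = _strip_ns(child.tag)
            if tag == "name" and child.text:
                bird = child.text.strip()
            elif tag == "number" and child.text:
                flight = int(child.text.strip())
            elif tag == "trkseg":
                for pt in child:
                    if _strip_ns(pt.tag) != "trkpt":
                        continue
                    try:
                        lat = float(pt.attrib["lat"])
                        lon = float(pt.attrib["lon"])
                    except (KeyError, ValueError):
                        raise ParseError(f"{path}: trkpt missing lat/lon in track {bird}") from None
                    time_el = next(
                        (el for el in pt if _strip_ns(el.tag) == "time"), None
                    )
                    if time_el is None or not time_el.text:
                        raise ParseError(f"{path}: trkpt without <time> in track {bird}")
                    ts_list.append(_parse_timestamp(time_el.text, str(path), 0))
                    lat_list.append(lat)
                    lon_list.append(lon)
        rows[(bird, flight)] = (ts_list, lat_list, lon_list)
    return _finish_tracks(rows)


def read_tracks(path: str | Path, format: str | None = None) -> list[RawTrack]:
    """Read GPS tracks from CSV or GPX 1.1; one RawTrack per (bird, flight).

    ``format`` is ``"csv"`` or ``"gpx"``; when omitted it is inferred from the
    file suffix.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "csv":
        return _read_csv(path)
    if format == "gpx":
        return _read_gpx(path)
    raise ValueError(f"unknown track format {format!r}")


def _iso(ts: float) -> str:
    return _dt.datetime.fromtimestamp(ts, tz=_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def write_tracks_csv(tracks: list[RawTrack], path: str | Path) -> None:
    """Write tracks in the package CSV dialect (ISO-8601 timestamps)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for tr in tracks:
            for ts, lat, lon in zip(tr.t, tr.lat, tr.lon):
                writer.writerow([tr.bird_id, tr.flight_number, _iso(ts), f"{lat:.7f}", f"{lon:.7f}"])


def write_tracks_gpx(tracks: list[RawTrack], path: str | Path) -> None:
    """Write tracks as GPX 1.1, one <trk> per flight."""
    root = ET.Element("gpx", attrib={"version": "1.1", "creator": "routegp", "xmlns": _GPX_NS})
    for tr in tracks:
        trk = ET.SubElement(root, "trk")
        ET.SubElement(trk, "name").text = tr.bird_id
        ET.SubElement(trk, "number").text = str(tr.flight_number)
        seg = ET.SubElement(trk, "trkseg")
        for ts, lat, lon in zip(tr.t, tr.lat, tr.lon):
            pt = ET.SubElement(seg, "trkpt", attrib={"lat": f"{lat:.7f}", "lon": f"{lon:.7f}"})
            ET.SubElement(pt, "time").text = _iso(ts)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def write_trajectories_csv(trajectories: list[Trajectory], path: str | Path) -> None:
    """Export model-ready trajectories: bird_id,flight,t,east_m,north_m."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bird_id", "flight", "t", "east_m", "north_m"])
        for tr in trajectories:
            for t, (e, n) in zip(tr.t, tr.xy):
                writer.writerow([tr.bird_id, tr.flight_number, f"{t:.10f}", f"{e:.4f}", f"{n:.4f}"])


# ---------------------------------------------------------------------------
# projection


def project_to_plane(track: RawTrack, origin: tuple[float, float]) -> PlanarTrack:
    """Project a raw track to local planar metres about ``origin`` (lat, lon).

    Local equirectangular: east = R cos(lat0) dlon, north = R dlat; the origin
    maps to (0, 0).  All samples must lie within 5 degrees of the origin.
    """
    lat0, lon0 = origin
    if np.any(np.abs(track.lat - lat0) > 5.0) or np.any(np.abs(track.lon - lon0) > 5.0):
        raise DomainError(
            f"track {track.bird_id}/{track.flight_number}: samples farther than 5 deg "
            "from projection origin; equirectangular approximation invalid"
        )
    east = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(track.lon - lon0)
    north = EARTH_RADIUS_M * np.radians(track.lat - lat0)
    return PlanarTrack(
        bird_id=track.bird_id,
        flight_number=track.flight_number,
        t=track.t.copy(),
        xy=np.column_stack([east, north]),
    )


def inverse_project(xy: np.ndarray, origin: tuple[float, float]) -> np.ndarray:
    """Map planar metres back to (lat, lon) degrees; exact inverse of the projection."""
    lat0, lon0 = origin
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    lat = lat0 + np.degrees(xy[:, 1] / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(xy[:, 0] / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    return np.column_stack([lat, lon])


# ---------------------------------------------------------------------------
# cleaning and resampling


def remove_stationary(
    track: PlanarTrack, speed_threshold: float = 1.0, window: float = 5.0
) -> PlanarTrack:
    """Delete contiguous stationary sections (e.g. the bird resting on the ground).

    A sample is seeded as stationary when the net displacement speed over a
    centred time window of length ``window`` seconds falls below
    ``speed_threshold`` m/s; each seeded run is then grown outward while the
    instantaneous step speed also stays below the threshold, so whole stops
    are removed rather than just their centres.  The first and last samples
    are always retained.
    """
    if speed_threshold <= 0:
        raise ValueError("speed_threshold must be > 0")
    n = track.t.shape[0]
    if n < 2:
        raise DegenerateTrackError("need at least 2 samples")
    t, xy = track.t, track.xy
    half = window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right") - 1
    hi = np.maximum(hi, np.minimum(lo + 1, n - 1))
    lo = np.minimum(lo, hi - 1)
    disp = np.linalg.norm(xy[hi] - xy[lo], axis=1)
    dt = t[hi] - t[lo]
    win_speed = disp / np.where(dt > 0, dt, np.inf)
    stationary = win_speed < speed_threshold

    # instantaneous step speeds, used to grow seeded runs to their true edges
    step = np.linalg.norm(np.diff(xy, axis=0), axis=1) / np.diff(t)
    slow_before = np.concatenate([[False], step < speed_threshold])
    slow_after = np.concatenate([step < speed_threshold, [False]])
    grown = stationary.copy()
    for _ in range(n):
        extend = (~grown) & (
            (np.concatenate([[False], grown[:-1]]) & slow_before)
            | (np.concatenate([grown[1:], [False]]) & slow_after)
        )
        if not extend.any():
            break
        grown |= extend

    if grown.all():
        raise DegenerateTrackError(
            f"track {track.bird_id}/{track.flight_number}: no motion above "
            f"{speed_threshold} m/s anywhere"
        )
    keep = ~grown
    keep[0] = keep[-1] = True
    return PlanarTrack(
        bird_id=track.bird_id, flight_number=track.flight_number, t=t[keep], xy=xy[keep]
    )


def normalize_and_resample(track: PlanarTrack, grid_size: int = 100) -> Trajectory:
    """Map time to a proportion of flight duration and resample onto a uniform grid.

    Time is mapped affinely so the first sample is 0 and the last is 1;
    positions are linearly interpolated onto ``grid_size`` equispaced points.
    All flights of a bird share this grid, which makes "observations at the
    same points in time" well defined across flights.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if track.t.shape[0] < 2:
        raise DegenerateTrackError("need at least 2 samples to normalize")
    duration = track.t[-1] - track.t[0]
    if duration <= 0:
        raise DegenerateTrackError("zero-duration track")
    t_norm = (track.t - track.t[0]) / duration
    t_norm[0], t_norm[-1] = 0.0, 1.0
    grid = np.linspace(0.0, 1.0, grid_size)
    east = np.interp(grid, t_norm, track.xy[:, 0])
    north = np.interp(grid, t_norm, track.xy[:, 1])
    return Trajectory(
        bird_id=track.bird_id,
        flight_number=track.flight_number,
        t=grid,
        xy=np.column_stack([east, north]),
    )


def beeline(site: SiteGeometry, t: np.ndarray) -> np.ndarray:
    """The straight release-to-loft line s(t) = release + t (loft - release).

    This is the symmetry-motivated prior mean of the habitual route: with no
    knowledge of the landscape there is no reason to expect deviation to
    either side of the direct line home.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0) or np.any(t > 1):
        raise DomainError("beeline times must lie in [0, 1]")
    return site.release[None, :] + t[:, None] * (site.loft - site.release)[None, :]
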