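"""Track ingestion: parsing, projection, cleaning, normalization."""

import numpy as np
import pytest

from routegp.errors import DegenerateTrackError, DomainError, ParseError, ValidationError
from routegp.tracks import (
    PlanarTrack,
    RawTrack,
    SiteGeometry,
    beeline,
    inverse_project,
    normalize_and_resample,
    project_to_plane,
    read_tracks,
    remove_stationary,
    write_tracks_csv,
    write_tracks_gpx,
)

ORIGIN = (51.78, -1.31)


def _write(tmp_path, text, name="tracks.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTracks:
    def test_csv_identity_readback(self, tmp_path):
        p = _write(
            tmp_path,
            "bird_id,flight,timestamp,lat,lon\n"
            "b1,1,0,51.8000000,-1.3000000\n"
            "b1,1,1,51.8000100,-1.3000100\n"
            "b1,1,2,51.8000200,-1.3000200\n",
        )
        tracks = read_tracks(p)
        assert len(tracks) == 1
        tr = tracks[0]
        assert (tr.bird_id, tr.flight_number, tr.n_samples) == ("b1", 1, 3)
        assert np.allclose(tr.t, [0, 1, 2])
        assert np.allclose(tr.lat, [51.8, 51.80001, 51.80002])

    def test_interleaved_flights_are_grouped_and_sorted(self, tmp_path):
        p = _write(
            tmp_path,
            "bird_id,flight,timestamp,lat,lon\n"
            "b1,2,10,51.8,-1.3\n"
            "b1,1,1,51.8,-1.3\n"
            "b1,2,11,51.8,-1.3\n"
            "b1,1,0,51.81,-1.3\n",
        )
        tracks = read_tracks(p)
        assert [(t.bird_id, t.flight_number) for t in tracks] == [("b1", 1), ("b1", 2)]
        assert np.all(np.diff(tracks[0].t) > 0)
        assert tracks[0].lat[0] == pytest.approx(51.81)  # sorted by time, not file order

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(
            tmp_path,
            "bird_id,flight,timestamp,lat,lon\nb1,1,0,51.8,-1.3\nb1,one,zzz,x,y\n",
        )
        with pytest.raises(ParseError, match=":3"):
            read_tracks(p)

    def test_duplicate_timestamps_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "bird_id,flight,timestamp,lat,lon\nb1,1,5,51.8,-1.3\nb1,1,5,51.81,-1.3\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_tracks(p)

    def test_iso8601_timestamps_accepted(self, tmp_path):
        p = _write(
            tmp_path,
            "bird_id,flight,timestamp,lat,lon\n"
            "b1,1,2009-01-01T00:00:00Z,51.8,-1.3\n"
            "b1,1,2009-01-01T00:00:01Z,51.8001,-1.3\n",
        )
        tr = read_tracks(p)[0]
        assert tr.t[1] - tr.t[0] == pytest.approx(1.0)

    def test_gpx_roundtrip_through_own_writer(self, tmp_path):
        tracks = [
            RawTrack("pigeon-7", 3, np.array([1.23e9, 1.23e9 + 1, 1.23e9 + 2]),
                     np.array([51.8, 51.80005, 51.8001]),
                     np.array([-1.31, -1.31001, -1.31002])),
        ]
        p = tmp_path / "t.gpx"
        write_tracks_gpx(tracks, p)
        back = read_tracks(p)
        assert len(back) == 1
        assert back[0].bird_id == "pigeon-7"
        assert back[0].flight_number == 3
        assert np.allclose(back[0].t, tracks[0].t, atol=1.0)
        assert np.allclose(back[0].lat, tracks[0].lat, atol=1e-6)
        assert np.allclose(back[0].lon, tracks[0].lon, atol=1e-6)

    def test_csv_roundtrip_through_own_writer(self, tmp_path):
        tracks = [
            RawTrack("b", 1, np.array([0.0, 1.0]), np.array([51.8, 51.81]),
                     np.array([-1.3, -1.31]))
        ]
        p = tmp_path / "t.csv"
        write_tracks_csv(tracks, p)
        back = read_tracks(p)
        assert np.allclose(back[0].lat, tracks[0].lat, atol=1e-6)


class TestProjection:
    def test_origin_maps_to_zero(self):
        tr = RawTrack("b", 1, np.array([0.0, 1.0]), np.array([ORIGIN[0], 51.8]),
                      np.array([ORIGIN[1], -1.3]))
        pl = project_to_plane(tr, ORIGIN)
        assert np.allclose(pl.xy[0], [0.0, 0.0], atol=1e-9)

    def test_latitude_degree_scale(self):
        # +0.01 deg latitude = R * 0.01 * pi/180 = 1111.95 m north
        tr = RawTrack("b", 1, np.array([0.0, 1.0]),
                      np.array([ORIGIN[0], ORIGIN[0] + 0.01]),
                      np.array([ORIGIN[1], ORIGIN[1]]))
        pl = project_to_plane(tr, ORIGIN)
        assert pl.xy[1, 1] == pytest.approx(1111.95, abs=0.01)
        assert pl.xy[1, 0] == pytest.approx(0.0, abs=1e-9)

    def test_project_inverse_project_roundtrip(self):
        tr = RawTrack("b", 1, np.array([0.0, 1.0]), np.array([51.75, 51.82]),
                      np.array([-1.35, -1.28]))
        pl = project_to_plane(tr, ORIGIN)
        latlon = inverse_project(pl.xy, ORIGIN)
        assert np.allclose(latlon[:, 0], tr.lat, atol=1e-9)
        assert np.allclose(latlon[:, 1], tr.lon, atol=1e-9)

    def test_far_from_origin_rejected(self):
        tr = RawTrack("b", 1, np.array([0.0, 1.0]), np.array([58.0, 58.0]),
                      np.array([-1.3, -1.31]))
        with pytest.raises(DomainError):
            project_to_plane(tr, ORIGIN)


def _toy_track(n_move=10, n_stop=30, speed=20.0, jitter=0.05, seed=0):
    """Moving / stationary / moving toy: 1 Hz, stop confined to < 1 m."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_move + n_stop + n_move, dtype=float)
    xy = np.zeros((t.shape[0], 2))
    for i in range(1, n_move):
        xy[i] = xy[i - 1] + [speed, 0.0]
    stop_at = xy[n_move - 1] + [speed, 0.0]
    for i in range(n_move, n_move + n_stop):
        xy[i] = stop_at + rng.uniform(-jitter, jitter, 2)
    xy[n_move + n_stop] = stop_at + [speed, 0.0]
    for i in range(n_move + n_stop + 1, t.shape[0]):
        xy[i] = xy[i - 1] + [speed, 0.0]
    return PlanarTrack("b", 1, t, xy)


class TestRemoveStationary:
    def test_constant_velocity_track_unchanged(self):
        t = np.arange(50, dtype=float)
        xy = np.column_stack([20.0 * t, np.zeros(50)])
        out = remove_stationary(PlanarTrack("b", 1, t, xy), 1.0, 5.0)
        assert out.t.shape[0] == 50

    def test_stationary_block_removed_entirely(self):
        track = _toy_track()
        out = remove_stationary(track, 1.0, 5.0)
        # the 30 stationary samples go; the 20 moving ones stay
        assert out.t.shape[0] == 20
        assert np.all(np.diff(out.t) > 0)

    def test_all_stationary_raises(self):
        t = np.arange(20, dtype=float)
        xy = np.full((20, 2), 3.0) + np.random.default_rng(1).uniform(-0.01, 0.01, (20, 2))
        with pytest.raises(DegenerateTrackError):
            remove_stationary(PlanarTrack("b", 1, t, xy), 1.0, 5.0)

    def test_endpoints_always_retained_and_order_preserved(self):
        track = _toy_track()
        out = remove_stationary(track, 1.0, 5.0)
        assert out.t[0] == track.t[0]
        assert out.t[-1] == track.t[-1]
        assert np.all(np.diff(out.t) > 0)


class TestNormalizeAndResample:
    def test_endpoints_and_uniform_spacing(self):
        t = np.arange(601, dtype=float)
        xy = np.column_stack([15.0 * t, 2.0 * t])
        traj = normalize_and_resample(PlanarTrack("b", 1, t, xy), 100)
        assert traj.t[0] == 0.0 and traj.t[-1] == 1.0
        assert traj.t.shape[0] == 100
        assert np.allclose(np.diff(traj.t), 1.0 / 99.0)

    def test_linear_motion_resamples_exactly_onto_segment(self):
        t = np.arange(0, 120, 1.0)
        v = np.array([12.0, -5.0])
        xy = t[:, None] * v[None, :]
        traj = normalize_and_resample(PlanarTrack("b", 1, t, xy), 50)
        seg = traj.t[:, None] * (xy[-1] - xy[0])[None, :] + xy[0]
        # perpendicular deviation from the chord is numerically zero
        assert np.abs(traj.xy - seg).max() < 1e-9

    def test_idempotent_on_gridded_input(self):
        t = np.arange(100, dtype=float)
        rng = np.random.default_rng(2)
        xy = rng.normal(size=(100, 2)).cumsum(axis=0) * 10
        first = normalize_and_resample(PlanarTrack("b", 1, t, xy), 100)
        second = normalize_and_resample(
            PlanarTrack("b", 1, first.t.copy(), first.xy.copy()), 100
        )
        assert np.abs(first.xy - second.xy).max() < 1e-12

    def test_zero_duration_raises(self):
        with pytest.raises((DegenerateTrackError, ValidationError)):
            normalize_and_resample(
                PlanarTrack("b", 1, np.array([5.0, 5.0]), np.zeros((2, 2))), 10
            )


class TestBeeline:
    def test_endpoints_and_midpoint(self):
        site = SiteGeometry(np.array([0.0, 0.0]), np.array([2000.0, -1000.0]), ORIGIN)
        assert np.allclose(beeline(site, np.array([0.0]))[0], site.release)
        assert np.allclose(beeline(site, np.array([1.0]))[0], site.loft)
        assert np.allclose(beeline(site, np.array([0.5]))[0], [1000.0, -500.0])

    def test_domain_error_outside_unit_interval(self):
        site = SiteGeometry(np.array([0.0, 0.0]), np.array([1.0, 0.0]), ORIGIN)
        with pytest.raises(DomainError):
            beeline(site, np.array([1.5]))
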