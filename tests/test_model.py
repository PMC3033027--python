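"""Hierarchical flight model: covariance anatomy, likelihoods, prediction."""

import numpy as np
import pytest

from routegp.gp import MaternParams, matern_kernel
from routegp.model import (
    FlightSet,
    Hyperparams,
    combined_covariance,
    flight_loglik_given_route,
    habitual_route_mean,
    joint_loglik,
    predict_flight,
)
from routegp.tracks import SiteGeometry, Trajectory, beeline
from routegp.simulate import SimConfig, sample_flights

from oracles import dense_joint_loglik, dense_mvn_loglik


def _traj(bird, flight, t, xy):
    return Trajectory(bird_id=bird, flight_number=flight, t=t, xy=xy)


class TestCombinedCovariance:
    def test_cross_flight_block_is_route_kernel_only(self, small_hyper):
        t1 = np.array([0.0, 0.3, 1.0])
        t2 = np.array([0.0, 0.5, 0.9, 1.0])
        sigma = combined_covariance([t1, t2], small_hyper)
        expected = matern_kernel(t1, t2, small_hyper.habitual)
        assert np.allclose(sigma[:3, 3:], expected, atol=1e-12)

    def test_diagonal_is_sum_of_zero_lag_variances(self, small_hyper):
        t = np.linspace(0, 1, 6)
        sigma = combined_covariance([t, t], small_hyper)
        h = small_hyper
        expected = (
            h.flight.output_scale**2 + h.habitual.output_scale**2 + h.noise_std**2
        )
        assert np.allclose(np.diag(sigma), expected)

    def test_single_flight_matches_term_by_term_sum(self, small_hyper):
        t = np.linspace(0, 1, 7)
        sigma = combined_covariance([t], small_hyper)
        by_hand = (
            matern_kernel(t, t, small_hyper.flight)
            + matern_kernel(t, t, small_hyper.habitual)
            + small_hyper.noise_std**2 * np.eye(7)
        )
        assert np.allclose(sigma, by_hand, atol=1e-12)

    def test_empty_flight_list_rejected(self, small_hyper):
        with pytest.raises(Exception):
            combined_covariance([], small_hyper)


class TestJointLoglik:
    def test_matches_dense_oracle_on_common_grid(self, flights, hyper):
        assert joint_loglik(flights, hyper) == pytest.approx(
            dense_joint_loglik(flights, hyper), rel=1e-8
        )

    def test_matches_dense_oracle_two_flights_five_points(self, site):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 1, 5)
        h = Hyperparams(MaternParams(150.0, 0.3), MaternParams(400.0, 0.2), 5.0)
        trajs = [
            _traj("b", i + 1, t, beeline(site, t) + 200 * rng.normal(size=(5, 2)))
            for i in range(2)
        ]
        fs = FlightSet(trajs, site)
        assert joint_loglik(fs, h) == pytest.approx(dense_joint_loglik(fs, h), rel=1e-8)

    def test_vanishing_route_variance_decouples_flights(self, site):
        rng = np.random.default_rng(12)
        t = np.linspace(0, 1, 20)
        h = Hyperparams(MaternParams(100.0, 0.3), MaternParams(1e-8, 0.2), 5.0)
        trajs = [
            _traj("b", i + 1, t, beeline(site, t) + 80 * rng.normal(size=(20, 2)))
            for i in range(3)
        ]
        fs = FlightSet(trajs, site)
        joint = joint_loglik(fs, h)
        independent = sum(
            flight_loglik_given_route(tr, beeline(site, t), h) for tr in trajs
        )
        assert joint == pytest.approx(independent, abs=1e-4)


class TestFlightLoglikGivenRoute:
    def test_single_point_closed_form(self):
        t = np.array([0.0, 1.0])
        xy = np.zeros((2, 2))
        h = Hyperparams(MaternParams(1.0, 0.3), MaternParams(1.0, 0.3), 0.0)
        tr = _traj("b", 1, t, xy)
        # residual zero: ll = 2 dims * -0.5*(logdet + n log 2pi)
        cov = matern_kernel(t, t, h.flight)
        _, logdet = np.linalg.slogdet(cov)
        expected = 2 * (-0.5 * (logdet + 2 * np.log(2 * np.pi)))
        assert flight_loglik_given_route(tr, xy, h) == pytest.approx(expected, rel=1e-6)

    def test_composition_matches_dense_gaussian(self, small_hyper):
        rng = np.random.default_rng(13)
        t = np.linspace(0, 1, 8)
        xy = rng.normal(size=(8, 2))
        route = rng.normal(size=(8, 2))
        tr = _traj("b", 1, t, xy)
        cov = matern_kernel(t, t, small_hyper.flight) + small_hyper.noise_std**2 * np.eye(8)
        expected = sum(
            dense_mvn_loglik(xy[:, d], route[:, d], cov) for d in range(2)
        )
        assert flight_loglik_given_route(tr, route, small_hyper) == pytest.approx(
            expected, rel=1e-8
        )

    def test_noise_increases_likelihood_of_far_outliers(self):
        t = np.linspace(0, 1, 10)
        xy = np.full((10, 2), 500.0)  # residual far beyond lambda
        tr = _traj("b", 1, t, xy)
        lls = [
            flight_loglik_given_route(
                tr,
                np.zeros((10, 2)),
                Hyperparams(MaternParams(10.0, 0.3), MaternParams(10.0, 0.3), eta),
            )
            for eta in [10.0, 50.0, 200.0]
        ]
        assert lls[0] < lls[1] < lls[2]

    def test_misaligned_route_rejected(self, small_hyper):
        tr = _traj("b", 1, np.array([0.0, 1.0]), np.zeros((2, 2)))
        with pytest.raises(Exception):
            flight_loglik_given_route(tr, np.zeros((3, 2)), small_hyper)


class TestPredictFlight:
    def test_prior_prediction_centred_on_beeline(self, site, hyper):
        q = np.linspace(0, 1, 25)
        pred = predict_flight(None, hyper, q, site)
        assert np.allclose(pred.mean, beeline(site, q))

    def test_matches_dense_joint_gaussian_oracle(self, site):
        rng = np.random.default_rng(14)
        t = np.linspace(0, 1, 8)
        h = Hyperparams(MaternParams(120.0, 0.3), MaternParams(300.0, 0.25), 5.0)
        trajs = [
            _traj("b", i + 1, t, beeline(site, t) + 150 * rng.normal(size=(8, 2)))
            for i in range(2)
        ]
        fs = FlightSet(trajs, site)
        q = np.array([0.1, 0.5, 0.85])
        pred = predict_flight(fs, h, q, site)

        # oracle: dense joint over [obs ∪ new] with explicit inverse
        t_all = np.concatenate([t, t])
        K_dd = matern_kernel(t_all, t_all, h.habitual)
        K_dd[:8, :8] += matern_kernel(t, t, h.flight)
        K_dd[8:, 8:] += matern_kernel(t, t, h.flight)
        K_dd += h.noise_std**2 * np.eye(16)
        K_qd = matern_kernel(q, t_all, h.habitual)
        K_qq = (
            matern_kernel(q, q, h.flight)
            + matern_kernel(q, q, h.habitual)
            + h.noise_std**2 * np.eye(3)
        )
        resid = np.concatenate([tr.xy - beeline(site, t) for tr in trajs])
        Kinv = np.linalg.inv(K_dd)
        mean = beeline(site, q) + K_qd @ Kinv @ resid
        cov = K_qq - K_qd @ Kinv @ K_qd.T
        assert np.allclose(pred.mean, mean, rtol=1e-8, atol=1e-8)
        assert np.allclose(pred.cov, cov, rtol=1e-8, atol=1e-8)

    def test_observed_beeline_flights_predict_beeline(self, site, hyper):
        t = np.linspace(0, 1, 15)
        trajs = [_traj("b", i + 1, t, beeline(site, t)) for i in range(3)]
        pred = predict_flight(FlightSet(trajs, site), hyper, t, site)
        assert np.abs(pred.mean - beeline(site, t)).max() < 1e-8

    def test_more_observed_flights_reduce_predictive_variance(self, site, hyper):
        cfg = SimConfig(site=site, hyper=hyper, n_flights=4, grid_size=20, seed=3)
        fs = sample_flights(cfg)
        q = np.array([0.5])
        var4 = predict_flight(fs, hyper, q, site).cov[0, 0]
        var2 = predict_flight(fs.subset([0, 1]), hyper, q, site).cov[0, 0]
        assert var4 <= var2 + 1e-10

    def test_dominant_route_pulls_prediction_to_flight_mean(self, site):
        # lambda_h >> lambda with tight noise: the habitual route dominates and
        # the predictive mean at observed times approaches the pointwise mean
        rng = np.random.default_rng(15)
        t = np.linspace(0, 1, 12)
        h = Hyperparams(MaternParams(1.0, 0.3), MaternParams(2000.0, 0.3), 0.5)
        trajs = [
            _traj("b", i + 1, t, beeline(site, t) + 500 * rng.normal(size=(1, 2)) * np.ones((12, 1)))
            for i in range(3)
        ]
        fs = FlightSet(trajs, site)
        pred = predict_flight(fs, h, t, site)
        pointwise = np.mean([tr.xy for tr in trajs], axis=0)
        assert np.abs(pred.mean - pointwise).max() < 25.0  # ~lambda_h/sqrt(n) shrinkage scale

    def test_query_outside_unit_interval_rejected(self, site, hyper):
        with pytest.raises(Exception):
            predict_flight(None, hyper, np.array([1.2]), site)

    def test_spatial_dimensions_are_exchangeable(self, site, hyper):
        cfg = SimConfig(site=site, hyper=hyper, n_flights=3, grid_size=15, seed=5)
        fs = sample_flights(cfg)
        q = np.linspace(0, 1, 15)
        pred = predict_flight(fs, hyper, q, site)
        # swap east/north everywhere (site and data): outputs swap identically
        site_sw = SiteGeometry(site.release[::-1].copy(), site.loft[::-1].copy(),
                               site.projection_origin)
        trajs_sw = [
            _traj(tr.bird_id, tr.flight_number, tr.t.copy(), tr.xy[:, ::-1].copy())
            for tr in fs.trajectories
        ]
        pred_sw = predict_flight(FlightSet(trajs_sw, site_sw), hyper, q, site_sw)
        assert np.allclose(pred_sw.mean, pred.mean[:, ::-1], atol=1e-8)
        assert np.allclose(pred_sw.cov, pred.cov, atol=1e-8)


class TestHabitualRouteMean:
    def test_fast_path_matches_dense_path(self, flights, hyper):
        q = np.linspace(0, 1, 11)
        fast = habitual_route_mean(flights, hyper, q)
        # force the dense branch by perturbing one time vector copy
        trajs = [t for t in flights.trajectories]
        dense_fs = FlightSet(trajs, flights.site)
        t_all = np.concatenate([tr.t for tr in trajs])
        sigma = combined_covariance([tr.t for tr in trajs], hyper)
        K_qD = matern_kernel(q, t_all, hyper.habitual)
        resid = np.concatenate(
            [tr.xy - beeline(flights.site, tr.t) for tr in trajs]
        )
        expected = beeline(flights.site, q) + K_qD @ np.linalg.inv(sigma) @ resid
        assert np.allclose(fast, expected, rtol=1e-7, atol=1e-6)
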