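import dataclasses

import numpy as np
import pytest

from walk6mwt._kalman import KalmanSpec, forward_filter, rts_smooth
from walk6mwt.estimators import (
    ALGORITHMS,
    AlphaBetaParams,
    alpha_beta_gains,
    distance_alpha_beta,
    distance_baseline,
    distance_kalman_1d,
    distance_kalman_2d,
    distance_kalman_smoothing,
    distance_qss,
    estimate_distance,
    preprocess_for,
)
from walk6mwt.simulate import NOISELESS, PathSpec, simulate_walk
from walk6mwt.trace import WalkTrace

from conftest import make_trace, straight_xy


def circle_xy(radius, speed, n):
    theta = np.cumsum(np.full(n, speed / radius))
    return np.column_stack([radius * np.cos(theta) - radius, radius * np.sin(theta)])


class TestBaseline:
    def test_two_samples(self):
        tr = make_trace([[0, 0], [0, 100]])
        assert distance_baseline(tr).distance_m == pytest.approx(100.0, rel=1e-6)

    def test_collinear_additivity(self):
        tr = make_trace([[0, 0], [0, 50], [0, 100]])
        assert distance_baseline(tr).distance_m == pytest.approx(100.0, rel=1e-6)

    def test_zero_noise_regular_walk(self):
        walk = simulate_walk(
            PathSpec(duration_s=360, speed_jitter_sd=0.0), NOISELESS, seed=0
        )
        assert walk.true_distance_m == pytest.approx(468.0, abs=1e-6)
        assert distance_baseline(walk.trace).distance_m == pytest.approx(468.0, rel=0.01)


class TestQss:
    def test_picks_lowest_accuracy_in_window(self):
        xy = straight_xy(11, speed=1.0)
        accs = [10, 5, 8, 9, 9, 9, 3, 9, 9, 9, 9]
        tr = make_trace(xy, acc=accs)
        res = distance_qss(tr)
        # windows [0,5), [5,10), [10,15) select the acc-5, acc-3 and last fixes
        assert res.n_samples_used == 3
        np.testing.assert_allclose(res.positions[0], tr.latlon()[1])
        np.testing.assert_allclose(res.positions[1], tr.latlon()[6])

    def test_straight_line_subsampling_lossless(self):
        tr = make_trace(straight_xy(61, speed=1.0))
        res = distance_qss(tr)
        assert res.distance_m == pytest.approx(60.0, abs=1e-6)

    def test_underestimates_circles_vs_baseline(self):
        tr = make_trace(circle_xy(5.0, 1.0, 120))
        assert distance_qss(tr).distance_m < distance_baseline(tr).distance_m

    def test_speed_gate(self):
        # second window's best fix is 30 m away after 5 s -> 6 m/s > 2 m/s gate
        xy = np.zeros((11, 2))
        xy[5:, 1] = 30.0
        tr = make_trace(xy, steps=False)
        res = distance_qss(tr)
        assert res.distance_m == pytest.approx(0.0, abs=1e-9)


class TestAlphaBetaGains:
    def test_zero_lambda(self):
        assert alpha_beta_gains(0.0) == (0.0, 0.0)

    def test_unit_lambda_closed_form(self):
        alpha, beta = alpha_beta_gains(1.0)
        assert alpha == pytest.approx(0.75, abs=1e-12)
        assert beta == pytest.approx(0.5, abs=1e-12)

    def test_large_lambda_limit(self):
        alpha, _ = alpha_beta_gains(1e6)
        assert alpha == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_lambda(self):
        lams = np.logspace(-3, 5, 50)
        gains = [alpha_beta_gains(l) for l in lams]
        alphas = [g[0] for g in gains]
        betas = [g[1] for g in gains]
        assert all(np.diff(alphas) >= 0)
        assert all(np.diff(betas) >= 0)
        assert all(0 <= a < 1 for a in alphas)


class TestAlphaBeta:
    def test_zero_accuracy_freezes_filter(self):
        tr = make_trace(straight_xy(30), acc=0.0)
        res = distance_alpha_beta(tr, AlphaBetaParams(acc_floor=0.0))
        assert res.distance_m == 0.0

    def test_huge_accuracy_tracks_measurements(self):
        tr = make_trace(straight_xy(60), acc=1e6)
        base = distance_baseline(tr).distance_m
        assert distance_alpha_beta(tr).distance_m == pytest.approx(base, rel=1e-3)

    def test_zero_noise_straight_walk_within_2pct(self):
        tr = make_trace(straight_xy(361))
        assert distance_alpha_beta(tr).distance_m == pytest.approx(1.3 * 360, rel=0.02)


class TestKalman1d:
    def test_zero_measurement_noise_reproduces_measurements(self, rng):
        xy = rng.normal(0, 20, size=(50, 2))
        tr = make_trace(xy, acc=0.0)
        res = distance_kalman_1d(tr)
        np.testing.assert_allclose(res.positions, tr.latlon(), atol=1e-9)

    def test_constant_position_velocity_converges(self):
        tr = make_trace(np.zeros((100, 2)), acc=5.0)
        # rebuild the filter to inspect terminal velocity
        from walk6mwt.trace import latlon_to_enu

        spec = KalmanSpec(
            A=np.array([[1.0, 1.0], [0.0, 1.0]]),
            Q=np.array([[36.0, 12.0], [12.0, 4.0]]),
            H=np.array([[1.0, 0.0]]),
        )
        zs = latlon_to_enu(tr.latlon())[:, 1].reshape(-1, 1)
        Rs = np.full((100, 1, 1), 25.0)
        xs, *_ = forward_filter(spec, zs, Rs, np.zeros(2), np.diag([25.0, 4.0]))
        assert abs(xs[-1, 1]) < 0.01

    def test_zero_noise_straight_walk_within_2pct(self):
        tr = make_trace(straight_xy(361))
        assert distance_kalman_1d(tr).distance_m == pytest.approx(468.0, rel=0.02)


class TestKalman2d:
    def test_zero_measurement_noise_reproduces_measurements(self, rng):
        xy = rng.normal(0, 20, size=(50, 2))
        tr = make_trace(xy, acc=0.0)
        res = distance_kalman_2d(tr)
        np.testing.assert_allclose(res.positions, tr.latlon(), atol=1e-9)

    def test_consistent_with_1d_on_straight_walks(self):
        tr = make_trace(straight_xy(200))
        d1 = distance_kalman_1d(tr).distance_m
        d2 = distance_kalman_2d(tr).distance_m
        assert d2 == pytest.approx(d1, rel=0.05)

    def test_zero_noise_straight_walk_within_2pct(self):
        tr = make_trace(straight_xy(361))
        assert distance_kalman_2d(tr).distance_m == pytest.approx(468.0, rel=0.02)


class TestKalmanSmoothing:
    def test_constant_measurements_stay_constant(self):
        tr = make_trace(np.zeros((60, 2)), acc=5.0, speed=0.0)
        res = distance_kalman_smoothing(tr)
        assert res.distance_m == pytest.approx(0.0, abs=1e-6)

    def test_rts_smoothing_beats_forward_filtering(self, rng):
        # linear-Gaussian track: the smoother is the optimal estimator
        n = 200
        q, r = 0.05, 4.0
        truth = np.cumsum(rng.normal(0, np.sqrt(q), n))
        zs = (truth + rng.normal(0, np.sqrt(r), n)).reshape(-1, 1)
        spec = KalmanSpec(A=np.eye(1), Q=np.array([[q]]), H=np.eye(1))
        Rs = np.full((n, 1, 1), r)
        xs, Ps, xps, Pps = forward_filter(spec, zs, Rs, zs[0], np.array([[r]]))
        xsm, _ = rts_smooth(spec, xs, Ps, xps, Pps)
        rmse_f = np.sqrt(np.mean((xs[:, 0] - truth) ** 2))
        rmse_s = np.sqrt(np.mean((xsm[:, 0] - truth) ** 2))
        assert rmse_s <= rmse_f

    def test_zero_noise_straight_walk_within_2pct(self):
        tr = make_trace(straight_xy(361), speed=1.3)
        assert distance_kalman_smoothing(tr).distance_m == pytest.approx(468.0, rel=0.02)


class TestSharedInvariants:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_single_sample_gives_zero(self, algorithm):
        tr = make_trace([[0.0, 0.0]])
        assert estimate_distance(tr, algorithm).distance_m == 0.0

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_timestamp_shift_invariance(self, algorithm):
        tr = make_trace(straight_xy(120))
        shifted = tr.with_samples(
            [dataclasses.replace(s, t=s.t + 86400.0) for s in tr.samples]
        )
        d0 = estimate_distance(tr, algorithm).distance_m
        d1 = estimate_distance(shifted, algorithm).distance_m
        assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_zero_noise_error_below_2pct_on_regular_paths(self, algorithm):
        walk = simulate_walk(PathSpec(duration_s=300), NOISELESS, seed=9)
        work = preprocess_for(algorithm, walk.trace)
        d = estimate_distance(work, algorithm).distance_m
        assert d == pytest.approx(walk.true_distance_m, rel=0.02)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            estimate_distance(make_trace(straight_xy(3)), "magic")
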