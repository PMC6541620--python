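"""Speeds, MSD (with brute-force oracle), classification, decay fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellquant.io_core import Track
from cellquant.motility import (
    MotilityError,
    SpeedSeries,
    average_speed,
    classify_motion,
    estimate_diffusion,
    fit_msd_linear,
    fit_speed_decay,
    mean_speed_series,
    msd,
    running_average_speed,
)
from cellquant.synthetic import TrajectorySpec, simulate_tracks

DT = 1.0 / 6.0


def _track(xs, ys, dt=DT, tid="t"):
    n = len(xs)
    return Track(
        track_id=tid,
        times=np.arange(n) * dt,
        xs=np.asarray(xs, dtype=float),
        ys=np.asarray(ys, dtype=float),
    )


def msd_bruteforce(tracks, max_lag):
    """O(n^2) double-loop oracle: time-average per track, then ensemble mean."""
    out = []
    for k in range(1, max_lag + 1):
        per_track = []
        for tr in tracks:
            vals = []
            for i in range(tr.n_points - k):
                dx = tr.xs[i + k] - tr.xs[i]
                dy = tr.ys[i + k] - tr.ys[i]
                vals.append(dx * dx + dy * dy)
            per_track.append(sum(vals) / len(vals))
        out.append(sum(per_track) / len(per_track))
    return np.array(out)


class TestAverageSpeed:
    def test_stationary_track_zero(self):
        assert average_speed(_track([0, 0, 0], [1, 1, 1])) == 0.0

    def test_constant_displacement_unit_arithmetic(self):
        # 5 um every 10 min -> 30 um/h
        xs = np.arange(5) * 5.0
        assert average_speed(_track(xs, np.zeros(5))) == pytest.approx(30.0)

    def test_hand_mean_of_three_steps(self):
        # displacements 1, 2, 3 um at dt = 1/6 h -> mean speed 12 um/h
        xs = [0.0, 1.0, 3.0, 6.0]
        assert average_speed(_track(xs, [0, 0, 0, 0])) == pytest.approx(12.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=2,
            max_size=20,
        ),
        st.floats(-np.pi, np.pi),
        st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
    )
    def test_invariant_under_rigid_motion(self, points, angle, shift):
        xs, ys = np.array([p[0] for p in points]), np.array([p[1] for p in points])
        base = average_speed(_track(xs, ys))
        c, s = np.cos(angle), np.sin(angle)
        xr = c * xs - s * ys + shift[0]
        yr = s * xs + c * ys + shift[1]
        assert average_speed(_track(xr, yr)) == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestRunningAverage:
    def test_constant_speed_flat_series(self):
        xs = np.arange(13) * 5.0  # 30 um/h for 2 h
        series = running_average_speed(_track(xs, np.zeros(13)))
        np.testing.assert_allclose(series.speeds_um_per_h, 30.0)
        assert series.window_centres_h.size == 2

    def test_fast_then_stopped_hand_windowing(self):
        xs = np.concatenate([np.arange(7) * 5.0, np.full(6, 30.0)])  # 1 h fast, 1 h stop
        series = running_average_speed(_track(xs, np.zeros(13)))
        np.testing.assert_allclose(series.speeds_um_per_h, [30.0, 0.0])

    def test_window_below_dt_rejected(self):
        with pytest.raises(MotilityError, match="window"):
            running_average_speed(_track([0, 1, 2], [0, 0, 0]), window_h=0.01)


class TestMSD:
    def test_stationary_tracks_zero(self):
        tracks = [_track(np.zeros(12), np.zeros(12))]
        assert np.all(msd(tracks).msd_um2 == 0.0)

    def test_four_point_track_hand_enumeration(self):
        # (0,0),(1,0),(1,1),(2,1): msd(dt)=1, msd(2dt)=2, msd(3dt)=5
        tr = _track([0, 1, 1, 2], [0, 0, 1, 1])
        r = msd([tr], max_lag_fraction=1.0)
        np.testing.assert_allclose(r.msd_um2, [1.0, 2.0, 5.0])
        np.testing.assert_array_equal(r.n_pairs, [3, 2, 1])

    def test_ballistic_closed_form(self):
        tracks, _ = simulate_tracks(
            TrajectorySpec(model="ballistic", speed_um_per_h=30.0, n_tracks=3, seed=0)
        )
        r = msd(tracks)
        np.testing.assert_allclose(r.msd_um2, (30.0 * r.lags_h) ** 2, rtol=1e-9)

    def test_matches_bruteforce_oracle_on_simulated_walks(self):
        tracks, _ = simulate_tracks(
            TrajectorySpec(n_tracks=5, duration_h=8.0, seed=2)
        )
        r = msd(tracks, max_lag_fraction=0.25)
        oracle = msd_bruteforce(tracks, r.lags_h.size)
        np.testing.assert_allclose(r.msd_um2, oracle, rtol=1e-10)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.integers(4, 50))
    def test_matches_bruteforce_oracle_property(self, seed, n_points):
        rng = np.random.default_rng(seed)
        tr = _track(rng.normal(0, 5, n_points), rng.normal(0, 5, n_points))
        r = msd([tr], max_lag_fraction=1.0)
        np.testing.assert_allclose(
            r.msd_um2, msd_bruteforce([tr], r.lags_h.size), rtol=1e-10
        )

    def test_ensemble_of_copies_equals_single_track(self):
        rng = np.random.default_rng(5)
        xs, ys = rng.normal(0, 5, 30), rng.normal(0, 5, 30)
        single = msd([_track(xs, ys)])
        copies = msd([_track(xs, ys, tid=f"c{i}") for i in range(4)])
        np.testing.assert_allclose(copies.msd_um2, single.msd_um2, rtol=1e-12)

    def test_empty_track_list_rejected(self):
        with pytest.raises(MotilityError):
            msd([])


class TestMSDFit:
    def test_exactly_linear_r2_one_slope_exact(self):
        from cellquant.motility import MSDResult

        lags = np.arange(1, 11) * DT
        result = MSDResult(
            lags_h=lags, msd_um2=3.0 * lags + 0.5, n_pairs=np.ones(10, int)
        )
        fit = fit_msd_linear(result)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(0.5)

    def test_random_walk_slope_recovers_4d(self):
        d_true = 50.0
        tracks, _ = simulate_tracks(
            TrajectorySpec(diffusion_um2_per_h=d_true, n_tracks=40, seed=8)
        )
        fit = fit_msd_linear(msd(tracks))
        assert fit.r_squared >= 0.99
        # 3-s.e. band from the per-lag scatter around the fitted line
        assert fit.slope == pytest.approx(4 * d_true, rel=0.15)

    def test_quadratic_msd_has_sub_unity_r2_and_curvature(self):
        from cellquant.motility import MSDResult

        lags = np.arange(1, 25) * DT
        result = fit_msd_linear(
            MSDResult(lags_h=lags, msd_um2=lags**2, n_pairs=np.ones(24, int))
        )
        assert result.r_squared < 1.0
        resid = result.msd_um2 - (result.slope * result.lags_h + result.intercept)
        # convex residual pattern: positive at both ends, negative in the middle
        assert resid[0] > 0 and resid[-1] > 0 and resid[len(resid) // 2] < 0

    def test_too_few_lags_rejected(self):
        from cellquant.motility import MSDResult

        with pytest.raises(MotilityError):
            fit_msd_linear(
                MSDResult(lags_h=np.array([DT]), msd_um2=np.array([1.0]),
                          n_pairs=np.array([1]))
            )


class TestClassification:
    def test_random_walk_diffusive(self):
        tracks, _ = simulate_tracks(TrajectorySpec(n_tracks=40, seed=4))
        assert classify_motion(msd(tracks)).label == "diffusive"

    def test_ballistic_superdiffusive_alpha_two(self):
        tracks, _ = simulate_tracks(TrajectorySpec(model="ballistic", seed=4))
        cls = classify_motion(msd(tracks))
        assert cls.label == "superdiffusive"
        assert cls.alpha == pytest.approx(2.0, abs=0.01)

    def test_stationary_flagged_degenerate(self):
        tracks = [_track(np.zeros(20), np.zeros(20))]
        cls = classify_motion(msd(tracks))
        assert cls.degenerate


class TestDiffusionEstimate:
    def test_short_lag_estimator_low_bias(self):
        tracks, _ = simulate_tracks(TrajectorySpec(n_tracks=40, seed=0))
        d_est = estimate_diffusion(tracks)
        assert d_est == pytest.approx(37.5, rel=0.05)


class TestSpeedDecay:
    def test_noiseless_half_life_round_trip(self):
        t = np.arange(0.5, 16, 1.0)
        s = 3.0 + 27.0 * 2.0 ** (-t / 1.7)
        fit = fit_speed_decay(SpeedSeries("m", t, s))
        assert fit.half_life_h == pytest.approx(1.7, rel=1e-4)
        assert fit.s0_um_per_h == pytest.approx(30.0, rel=1e-3)
        assert fit.s_inf_um_per_h == pytest.approx(3.0, rel=1e-3)

    def test_post_drug_offset_handled(self):
        t = np.arange(0.5, 22, 1.0)
        s = np.where(t < 6.0, 30.0, 3.0 + 27.0 * 2.0 ** (-(t - 6.0) / 2.5))
        fit = fit_speed_decay(SpeedSeries("m", t, s), t_drug_h=6.0)
        assert fit.half_life_h == pytest.approx(2.5, rel=1e-3)

    def test_constant_series_flagged_unidentifiable(self):
        t = np.arange(0.5, 10, 1.0)
        fit = fit_speed_decay(SpeedSeries("m", t, np.full_like(t, 12.0)))
        assert not fit.identifiable
        assert np.isnan(fit.half_life_h)

    def test_simulated_washout_recovery_with_noise(self):
        errs = []
        for seed in range(5):
            tracks, _ = simulate_tracks(
                TrajectorySpec(
                    model="decaying_speed", n_tracks=40, seed=seed,
                    speed_noise_frac=0.10,
                )
            )
            series = mean_speed_series(
                [running_average_speed(tr) for tr in tracks]
            )
            fit = fit_speed_decay(series)
            errs.append(abs(fit.half_life_h / 1.7 - 1))
        assert max(errs) < 0.15

    def test_too_few_windows_rejected(self):
        with pytest.raises(MotilityError):
            fit_speed_decay(SpeedSeries("m", np.array([0.5, 1.5, 2.5]),
                                        np.array([3.0, 2.0, 1.0])))
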