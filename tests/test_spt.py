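"""MSD estimator vs brute force, model fits on exact curves, gyration
geometry, the four-class decision protocol, and export-event timing."""

import numpy as np
import pandas as pd
import pytest

from embryotrace import synth
from embryotrace.spt import (
    MSDCurve,
    Trajectory,
    classify_motion,
    compute_msd,
    directed_transit_estimate,
    export_transit,
    filter_tracks,
    fit_directed,
    fit_models,
    gyration_ratio,
    max_displacement,
    tracks_from_table,
)
from conftest import brute_force_msd


def _table(track_id, n, dt=0.01, x=None, y=None):
    x = np.zeros(n) if x is None else x
    y = np.zeros(n) if y is None else y
    return pd.DataFrame({
        "track_id": track_id, "frame": np.arange(n),
        "t_s": dt * np.arange(n), "x_um": x, "y_um": y,
    })


class TestFilterTracks:
    def test_19_frame_track_removed_20_frame_kept(self):
        df = pd.concat([_table("short", 19), _table("ok", 20)], ignore_index=True)
        kept = filter_tracks(df, min_frames=20)
        assert set(kept["track_id"]) == {"ok"}

    def test_gappy_track_judged_on_longest_run(self):
        df = _table("gap", 30)
        df = df[df["frame"] != 15]  # 15 + 14 consecutive
        assert filter_tracks(df, min_frames=20).empty

    def test_empty_table_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = filter_tracks(_table("x", 0), 20)
        assert out.empty

    def test_malformed_rows_reported_with_line_numbers(self):
        df = _table("t", 25)
        df.loc[3, "x_um"] = np.nan
        with pytest.raises(ValueError, match="lines \\[5\\]"):
            filter_tracks(df)


class TestComputeMsd:
    def test_identical_positions_give_zero_msd(self):
        traj = Trajectory("t", np.zeros((30, 2)), 0.01)
        assert np.allclose(compute_msd(traj, 10).msd, 0.0)

    def test_straight_line_msd_is_vt_squared(self):
        v, dt = 2.0, 0.01
        t = dt * np.arange(50)
        traj = Trajectory("t", np.column_stack([v * t, np.zeros(50)]), dt)
        curve = compute_msd(traj, 10)
        assert np.allclose(curve.msd, (v * curve.lags_s) ** 2)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        traj = Trajectory("t", rng.normal(size=(80, 2)), 0.01)
        curve = compute_msd(traj, 25)
        assert np.allclose(curve.msd, brute_force_msd(traj.positions, 25))

    def test_brownian_msd_lag1(self):
        params = synth.TrajectoryParams("diffusive", D_micro=0.25, n_frames=200,
                                        dt=0.01, seed=0)
        trajs = synth.gen_trajectories(params, 100)
        lag1 = np.mean([compute_msd(t, 1).msd[0] for t in trajs])
        assert lag1 == pytest.approx(4 * 0.25 * 0.01, rel=0.05)

    def test_excess_lag_truncated_with_warning(self):
        traj = Trajectory("t", np.zeros((10, 2)), 0.01)
        with pytest.warns(UserWarning, match="truncating"):
            curve = compute_msd(traj, 50)
        assert len(curve.msd) == 9


class TestGyrationRatio:
    def test_collinear_points_are_fully_anisotropic(self):
        pos = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        assert gyration_ratio(Trajectory("t", pos, 1.0)) == pytest.approx(0.0, abs=1e-12)

    def test_square_corners_are_isotropic(self):
        pos = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert gyration_ratio(Trajectory("t", pos, 1.0)) == pytest.approx(1.0)

    def test_three_point_hand_eigendecomposition(self):
        # covariance of (0,0),(1,0),(1,1) has eigenvalues 1/3 and 1/9,
        # so the radii ratio is sqrt(1/3)
        pos = np.array([[0, 0], [1, 0], [1, 1]], float)
        assert gyration_ratio(Trajectory("t", pos, 1.0)) == pytest.approx(
            np.sqrt(1 / 3)
        )

    def test_degenerate_track_is_isotropic_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert gyration_ratio(Trajectory("t", np.ones((5, 2)), 1.0)) == 1.0


class TestFitModels:
    def test_exact_confined_curve_recovered_within_1pct(self):
        L, tau = 0.5, 0.074
        t = 0.01 * np.arange(1, 11)
        msd = MSDCurve(t, (L**2 / 3) * (1 - np.exp(-t / tau)), np.full(10, 99), 0.01)
        fit = fit_models(msd, 10)["confined"]
        assert fit.L == pytest.approx(L, rel=0.01)
        assert fit.tau == pytest.approx(tau, rel=0.01)
        assert fit.D == pytest.approx(L**2 / (12 * tau), rel=0.01)

    def test_exact_linear_msd_gives_alpha_1_and_D(self):
        D = 0.3
        t = 0.01 * np.arange(1, 11)
        msd = MSDCurve(t, 4 * D * t, np.full(10, 99), 0.01)
        fit = fit_models(msd, 10)["powerlaw"]
        assert fit.alpha == pytest.approx(1.0, abs=0.01)
        assert fit.D == pytest.approx(D, rel=0.01)

    def test_ballistic_curve_drives_alpha_to_2(self):
        v = 3.0
        t = 0.01 * np.arange(1, 11)
        msd = MSDCurve(t, (v * t) ** 2, np.full(10, 99), 0.01)
        fit = fit_models(msd, 10)["powerlaw"]
        assert fit.alpha == pytest.approx(2.0, abs=0.01)
        assert fit_directed(msd, 10).v == pytest.approx(v, rel=1e-6)

    def test_too_few_lags_rejected(self):
        t = 0.01 * np.arange(1, 4)
        with pytest.raises(ValueError):
            fit_models(MSDCurve(t, t, np.full(3, 9), 0.01), 3)


class TestClassifyMotion:
    def test_directed_track_classified_directed(self):
        params = synth.TrajectoryParams("directed", D_micro=0.0, v=3.2,
                                        sigma_loc=0.0, n_frames=100, dt=0.01,
                                        seed=1)
        fit = classify_motion(synth.gen_trajectory(params))
        assert fit.motion_class == "directed"
        assert fit.v == pytest.approx(3.2, rel=0.01)

    def test_stationary_track_with_localization_noise(self):
        params = synth.TrajectoryParams("stationary", sigma_loc=0.02,
                                        n_frames=100, dt=0.01, seed=2)
        fit = classify_motion(synth.gen_trajectory(params))
        assert fit.motion_class == "stationary"

    def test_stationary_override_never_fires_on_large_D(self):
        # noise sigma 20 nm never produces an apparent D above 0.03 um^2/s
        for seed in range(100):
            params = synth.TrajectoryParams("stationary", sigma_loc=0.02,
                                            n_frames=100, dt=0.01, seed=seed)
            fit = classify_motion(synth.gen_trajectory(params))
            assert fit.motion_class == "stationary"

    def test_classification_is_exclusive_and_exhaustive(self):
        labels = {"stationary", "corralled", "diffusive", "directed",
                  "unclassified"}
        for cls, kw in (("diffusive", {}), ("corralled", {"L_box": 0.5}),
                        ("directed", {"v": 3.0, "D_micro": 0.0}),
                        ("stationary", {"sigma_loc": 0.02})):
            params = synth.TrajectoryParams(cls, n_frames=200, dt=0.01, seed=3,
                                            **kw)
            fit = classify_motion(synth.gen_trajectory(params))
            assert fit.motion_class in labels


class TestExportTransit:
    # square "nucleus" with its right edge at x=5
    BOUNDARY = np.array([[0, 0], [5, 0], [5, 5], [0, 5]], float)

    def _track(self, xs, ys=None, dt=0.01):
        ys = np.full(len(xs), 2.5) if ys is None else ys
        return Trajectory("t", np.column_stack([xs, ys]), dt)

    def test_scripted_dwell_then_cross_measures_dwell_time(self):
        # 50 frames dwelling 0.1 um inside the edge, then marching out
        xs = np.concatenate([np.full(50, 4.9), 5.05 + 0.2 * np.arange(10)])
        event = export_transit(self._track(xs), self.BOUNDARY)
        assert event is not None
        assert event.transit_s == pytest.approx(0.5, abs=0.02)
        assert event.mode in ("fast", "directed")

    def test_instant_crossing_has_transit_at_most_dt(self):
        xs = np.concatenate([np.linspace(3.0, 4.95, 20),
                             5.1 + 0.3 * np.arange(10)])
        event = export_transit(self._track(xs), self.BOUNDARY)
        assert event is not None
        assert event.transit_s <= 2 * 0.01 + 1e-9

    def test_slow_event_classified_slow(self):
        xs = np.concatenate([np.full(150, 4.9), 5.05 + 0.2 * np.arange(10)])
        ys = 2.5 + np.random.default_rng(0).normal(0, 0.02, len(xs))
        event = export_transit(self._track(xs, ys, dt=0.01), self.BOUNDARY)
        assert event.transit_s >= 1.0 and event.mode == "slow"

    def test_track_never_crossing_yields_none(self):
        xs = np.linspace(1.0, 4.0, 30)
        assert export_transit(self._track(xs), self.BOUNDARY) is None

    def test_cohort_dwell_times_recovered_within_one_frame(self):
        # scripted events with dwell times spanning the observed 0.1-30 s range
        dt = 0.05
        rng = np.random.default_rng(4)
        for dwell_s in (0.1, 1.0, 7.5, 30.0):
            n_dwell = int(round(dwell_s / dt))
            xs = np.concatenate([
                np.linspace(3.0, 4.85, 10),
                4.9 + rng.normal(0, 0.01, n_dwell),
                5.05 + 0.3 * np.arange(8),
            ])
            event = export_transit(self._track(xs, dt=dt), self.BOUNDARY)
            assert event is not None
            assert event.transit_s == pytest.approx(dwell_s, abs=3 * dt)


class TestDirectedTransitEstimate:
    def test_infinite_speed_limit(self):
        assert directed_transit_estimate(1e12) == pytest.approx(0.0, abs=1e-9)

    def test_cytoplasmic_directed_speed_gives_141_ms(self):
        assert directed_transit_estimate(1.4193, 0.2) == pytest.approx(0.141, abs=0.001)

    def test_simple_arithmetic(self):
        assert directed_transit_estimate(2.0, 0.2) == pytest.approx(0.1)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            directed_transit_estimate(0.0)


class TestTableRoundTrip:
    def test_tracks_from_table_preserves_positions(self):
        params = synth.TrajectoryParams("diffusive", n_frames=30, seed=5)
        trajs = [synth.gen_trajectory(params, track_id=i) for i in range(3)]
        table = pd.concat([t.to_dataframe() for t in trajs], ignore_index=True)
        back = tracks_from_table(table, dt=0.01)
        for a, b in zip(trajs, back):
            assert np.allclose(a.positions, b.positions)

    def test_max_displacement_matches_pairwise_scan(self):
        rng = np.random.default_rng(6)
        pos = rng.normal(size=(40, 2))
        traj = Trajectory("t", pos, 0.01)
        brute = max(
            np.linalg.norm(pos[i] - pos[j])
            for i in range(40) for j in range(i + 1, 40)
        )
        assert max_displacement(traj) == pytest.approx(brute)
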