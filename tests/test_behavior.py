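import numpy as np
import pytest

from vrstress.behavior import (
    build_feature_table,
    detect_bursts,
    detect_gait_cycles,
    gait_features,
    head_scan_count,
    kinematics_features,
    position_features_ea,
    position_features_er,
    trajectory_shape_features,
)
from vrstress.behavior.gait import GaitEvents
from vrstress.core import FootTracks
from vrstress.errors import InsufficientDataError, InvalidArgumentError, SchemaError
from vrstress.synth import generate_cohort, simulate_gait
from vrstress.synth.traits import TraitProfile

from conftest import make_trajectory

RATE = 90.0


def _t(duration=90.0):
    return np.arange(0, duration, 1 / RATE)


# ----------------------------------------------------------------- position
class TestPositionER:
    def test_corner_pin(self, geometry):
        traj = make_trajectory(_t(), 0.0, 0.0)
        f = position_features_er(traj, geometry)
        assert f["corner_dist_min"] == 0.0
        assert f["time_center"] == 0.0
        assert f["latency_first_center_entry"] == pytest.approx(90.0, abs=0.1)

    def test_center_pin(self, geometry):
        traj = make_trajectory(_t(), 1.75, 3.0)
        f = position_features_er(traj, geometry)
        assert f["corner_dist_min"] == pytest.approx(np.sqrt(1.75**2 + 3.0**2))
        assert f["corner_dist_min"] == pytest.approx(3.473, abs=0.001)
        assert f["time_periphery"] == 0.0

    def test_center_only_ratio_capped_and_warned(self, geometry):
        traj = make_trajectory(_t(), 1.75, 3.0)
        with pytest.warns(UserWarning, match="capped"):
            f = position_features_er(traj, geometry)
        assert f["ratio_time_center_periphery"] == pytest.approx(90.0 * RATE, rel=0.01)

    def test_out_of_bounds_rejected(self, geometry):
        traj = make_trajectory(_t(1.0), 5.0, 3.0)
        with pytest.raises(InvalidArgumentError):
            position_features_er(traj, geometry)

    def test_time_features_bounded(self, geometry, small_cohort):
        traj = small_cohort[0].sessions["empty_room"].head_track
        f = position_features_er(traj, geometry)
        dur = 90.0
        half_diag = np.hypot(1.75, 3.0)
        assert 0.0 <= f["corner_dist_min"] <= half_diag + 1e-6
        for key in ("time_center", "time_periphery", "latency_first_center_entry"):
            assert 0.0 <= f[key] <= dur + 0.2


class TestPositionEA:
    def test_never_leaves_board(self, geometry):
        traj = make_trajectory(_t(), 1.75, 0.5)
        f = position_features_ea(traj, geometry)
        assert f["time_board"] == pytest.approx(90.0, abs=0.1)
        assert f["time_narrow"] == 0.0
        assert f["max_longitudinal"] == pytest.approx(0.5)
        assert f["first_cross_1"] == pytest.approx(90.0, abs=0.1)  # censored

    def test_scripted_traverse_crossing_times(self, geometry):
        # constant 0.5 m/s along the alley from y=0
        t = _t(12.0)
        traj = make_trajectory(t, 1.75, 0.5 * t)
        f = position_features_ea(traj, geometry)
        assert f["first_cross_1"] == pytest.approx(1.5 / 0.5, abs=0.05)
        assert f["first_cross_2"] == pytest.approx(3.0 / 0.5, abs=0.05)
        assert f["first_cross_3"] == pytest.approx(4.5 / 0.5, abs=0.05)
        assert f["n_retreats"] == 0.0

    def test_patch_dwell_sums_to_duration(self, geometry, small_cohort):
        traj = small_cohort[1].sessions["elevated_alley"].head_track
        f = position_features_ea(traj, geometry)
        total = sum(f[f"time_patch_{k}"] for k in range(1, 5))
        assert total == pytest.approx(traj.n * traj.dt, rel=0.01)

    def test_retreat_counting(self, geometry):
        t = _t(30.0)
        # out to 3 m, back to 1 m, out to 4 m, back to 2 m: 2 retreats
        knots_t = [0, 6, 10, 16, 20, 30]
        knots_y = [0, 3.0, 1.0, 4.0, 2.0, 2.0]
        y = np.interp(t, knots_t, knots_y)
        traj = make_trajectory(t, 1.75, y)
        f = position_features_ea(traj, geometry)
        assert f["n_retreats"] == 2.0


# --------------------------------------------------------------- kinematics
class TestKinematics:
    def test_stationary(self, stationary_traj):
        f = kinematics_features(stationary_traj)
        assert f["speed_mean"] == pytest.approx(0.0, abs=1e-9)
        assert f["horiz_acc_rms"] == pytest.approx(0.0, abs=1e-9)
        assert f["path_length"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_velocity_line(self):
        t = _t(10.0)
        traj = make_trajectory(t, 0.5 + 0.3 * t, 1.0)
        f = kinematics_features(traj)
        assert f["speed_mean"] == pytest.approx(0.3, rel=0.02)
        assert f["horiz_acc_rms"] < 0.02
        assert f["path_length"] == pytest.approx(0.3 * 10.0, rel=0.02)

    def test_vertical_sinusoid_closed_form(self):
        # z = A sin(2 pi f t) -> RMS vertical acceleration = A (2 pi f)^2 / sqrt(2),
        # times the attenuation of the 0.5 s moving-average smoother
        A, freq = 0.05, 1.0
        t = _t(30.0)
        traj = make_trajectory(t, 1.0, 1.0, z=1.7 + A * np.sin(2 * np.pi * freq * t))
        f = kinematics_features(traj)
        win = round(0.5 * RATE) / RATE
        atten = np.abs(np.sinc(freq * win))
        expected = A * (2 * np.pi * freq) ** 2 / np.sqrt(2) * atten
        assert f["vert_acc_rms"] == pytest.approx(expected, rel=0.05)

    def test_too_few_samples(self):
        traj = make_trajectory([0.0, 0.1], [0, 0.1], [0, 0.1])
        with pytest.raises(InsufficientDataError):
            kinematics_features(traj)


# -------------------------------------------------------------------- shape
class TestShape:
    def test_single_cell_focus_one(self, geometry, stationary_traj):
        f = trajectory_shape_features(stationary_traj, geometry)
        assert f["focus"] == 1.0

    def test_uniform_spread_focus_near_zero(self, geometry):
        # equal dwell in each cell of a 10x10 block of 0.25 m cells
        cells = [(i, j) for i in range(10) for j in range(10)]
        xs = np.repeat([0.125 + 0.25 * i for i, _ in cells], 9)
        ys = np.repeat([0.125 + 0.25 * j for _, j in cells], 9)
        t = np.arange(xs.size) / RATE
        f = trajectory_shape_features(make_trajectory(t, xs, ys), geometry)
        assert f["focus"] == pytest.approx(0.0, abs=0.02)

    def test_circular_path_concentric(self, geometry):
        t = _t(60.0)
        theta = 2 * np.pi * t / 20.0
        x = 1.75 + 1.2 * np.cos(theta)
        y = 3.0 + 1.2 * np.sin(theta)
        f = trajectory_shape_features(make_trajectory(t, x, y), geometry)
        assert f["concentric"] >= 0.99

    def test_radial_path_not_concentric(self, geometry):
        t = _t(20.0)
        traj = make_trajectory(t, 1.75, 0.5 + 0.25 * t)  # straight at the center
        f = trajectory_shape_features(traj, geometry)
        assert f["concentric"] <= 0.1


class TestHeadScans:
    def _walking(self, duration=60.0):
        t = _t(duration)
        x = 0.5 + 0.04 * t  # slow drift; speed boosted below via y
        y = 0.3 + 0.4 * t % 5.0
        return t

    def test_yaw_locked_to_heading(self):
        t = _t(30.0)
        traj = make_trajectory(t, 0.5 + 0.3 * t, 1.0, yaw=0.0)  # heading = 0 deg
        f = head_scan_count(traj)
        assert f["head_scan_count"] == 0.0

    def test_five_scripted_scans_counted(self):
        # straight walk along y at 0.35 m/s with five scripted 40 deg pulses
        t = _t(15.0)
        y = 0.2 + 0.35 * t
        yaw = np.full_like(t, 90.0)  # heading for +y motion
        for k in range(5):
            i0 = int((1.5 + 2.5 * k) * RATE)
            yaw[i0 : i0 + int(1.0 * RATE)] += 40.0
        traj = make_trajectory(t, 1.0, y, yaw=yaw)
        f = head_scan_count(traj)
        assert f["head_scan_count"] == 5.0

    def test_scans_while_stationary_ignored(self):
        t = _t(30.0)
        yaw = np.zeros_like(t)
        for k in range(3):
            i0 = int((5 + 8 * k) * RATE)
            yaw[i0 : i0 + int(1.0 * RATE)] = 40.0
        traj = make_trajectory(t, 1.0, 1.0, yaw=yaw)
        f = head_scan_count(traj)
        assert f["head_scan_count"] == 0.0


# --------------------------------------------------------------------- gait
def _profile(**kw):
    base = dict(
        vulnerability=0.0, thigmotaxis_bias=0.5, center_avoidance=0.5,
        gait_speed_cv=0.1, mean_nn=800.0, nn_sd=40.0, rsa_amplitude=20.0,
        resp_rate=15.0, walk_speed=0.6,
    )
    base.update(kw)
    return TraitProfile(**base)


class TestGaitDetection:
    def test_stationary_feet_no_strides(self):
        t = np.arange(0, 10, 1 / 60)
        still = np.tile([0.5, 1.0, 0.0], (t.size, 1))
        events = detect_gait_cycles(FootTracks(t=t, left=still, right=still.copy()))
        assert events.n_strides == 0
        assert gait_features(events)["stride_count"] == 0.0

    @staticmethod
    def _triangular_walk(duration=60.0, speed=0.3):
        # back-and-forth walk along the room length at constant speed
        t = np.arange(0, duration, 1 / RATE)
        period = 2 * 5.0 / speed
        phase = (t % period) / period
        y = 0.4 + 5.0 * np.where(phase < 0.5, 2 * phase, 2 * (1 - phase))
        return make_trajectory(t, 1.0, y)

    def test_recovers_scripted_gait(self):
        head = self._triangular_walk()
        tracks, truth = simulate_gait(head, _profile(), seed=0)
        events = detect_gait_cycles(tracks)
        true_all = np.sort(
            np.concatenate([truth["heel_strikes"]["left"],
                            truth["heel_strikes"]["right"]])
        )
        det = events.all_strikes
        d = np.abs(det[:, None] - true_all[None, :])
        recovery = (d.min(axis=0) < 0.1).mean()
        assert recovery >= 0.95

    def test_constant_speed_low_cv(self):
        head = self._triangular_walk()
        tracks, _ = simulate_gait(head, _profile(), seed=0)
        feats = gait_features(detect_gait_cycles(tracks))
        assert feats["stride_speed_cv"] < 0.2

    def test_stance_fraction_in_unit_interval(self, small_cohort):
        events = detect_gait_cycles(small_cohort[0].sessions["empty_room"].foot_tracks)
        for s in events.strides:
            assert 0.0 < s.stance_fraction < 1.0
            # stance + swing partition the stride by construction
            stance = s.stance_fraction * s.duration
            swing = (1 - s.stance_fraction) * s.duration
            assert stance + swing == pytest.approx(s.duration)


class TestBursts:
    def test_two_groups_two_bursts(self, stationary_traj):
        strikes = np.concatenate([np.arange(0.0, 5.0, 0.7),
                                  np.arange(10.0, 15.0, 0.7)])
        events = GaitEvents()
        events.heel_strikes["left"] = strikes[::2]
        events.heel_strikes["right"] = strikes[1::2]
        f = detect_bursts(events, stationary_traj)
        assert f["burst_count"] == 2.0

    def test_uninterrupted_walk_single_burst(self):
        traj = TestGaitDetection._triangular_walk()
        events = GaitEvents()
        strikes = np.arange(0.0, 60.0, 0.6)
        events.heel_strikes["left"] = strikes[::2]
        events.heel_strikes["right"] = strikes[1::2]
        f = detect_bursts(events, traj)
        assert f["burst_count"] == 1.0
        assert f["immobility_total"] == 0.0

    def test_no_cycles_full_immobility(self, stationary_traj):
        f = detect_bursts(GaitEvents(), stationary_traj)
        assert f["burst_count"] == 0.0
        assert f["immobility_total"] == pytest.approx(30.0, abs=0.5)


# -------------------------------------------------------------------- table
class TestFeatureTable:
    def test_build_from_cohort(self, small_cohort):
        sessions = {s.subject_id: s.sessions for s in small_cohort}
        table = build_feature_table(sessions)
        assert table.data.shape[0] == len(small_cohort)
        for col in table.columns:
            assert table.families[col] in ("position", "gait", "burst")
            assert table.scenarios[col] in ("er", "ea")
        # all nine headline feature analogues present
        for name in (
            "corner_dist_min_er", "vert_acc_rms_ea",
            "ratio_time_center_periphery_er", "time_narrow_ea", "focus_er",
            "stride_speed_cv_er", "head_scan_count_er", "time_board_ea",
            "max_longitudinal_ea",
        ):
            assert name in table.columns, name

    def test_missing_mocap_flags_gait_only(self, small_cohort):
        sessions = {s.subject_id: dict(s.sessions) for s in small_cohort}
        sid = small_cohort[0].subject_id
        er = sessions[sid]["empty_room"]
        import dataclasses

        sessions[sid]["empty_room"] = dataclasses.replace(er, foot_tracks=None)
        table = build_feature_table(sessions)
        row = table.data.loc[sid]
        gait_cols = [c for c in table.columns
                     if table.families[c] == "gait" and c.endswith("_er")]
        assert row[gait_cols].isna().all()
        assert np.isfinite(row["corner_dist_min_er"])

    def test_deterministic_rebuild(self, small_cohort):
        sessions = {s.subject_id: s.sessions for s in small_cohort}
        a = build_feature_table(sessions)
        b = build_feature_table(sessions)
        assert a.data.equals(b.data)

    def test_duplicate_ids_rejected(self, small_cohort):
        class WeirdDict(dict):
            def __iter__(self):
                yield from list(super().__iter__()) * 2

        sessions = WeirdDict({s.subject_id: s.sessions for s in small_cohort})
        with pytest.raises(SchemaError):
            build_feature_table(sessions)


def test_resampling_robustness(geometry, small_cohort):
    """Smooth-path features agree within 5% between 90 Hz and 45 Hz."""
    t = np.arange(0, 60, 1 / 90)
    x = 1.75 + 1.0 * np.cos(2 * np.pi * t / 25.0)
    y = 3.0 + 2.0 * np.sin(2 * np.pi * t / 25.0)
    traj90 = make_trajectory(t, x, y)
    traj45 = traj90.resample(45.0)
    for func in (
        lambda tr: kinematics_features(tr),
        lambda tr: position_features_er(tr, geometry),
    ):
        f90 = func(traj90)
        f45 = func(traj45)
        for key, v90 in f90.items():
            v45 = f45[key]
            if abs(v90) < 1e-6:
                assert abs(v45) < 0.05
            else:
                assert v45 == pytest.approx(v90, rel=0.05), key


def test_thigmotaxis_monotonicity(geometry):
    """Higher generator wall bias means less expected center time."""
    from vrstress.synth import simulate_trajectory

    def center_time(bias, seeds=range(5)):
        prof = _profile(thigmotaxis_bias=bias, center_avoidance=bias)
        vals = []
        for seed in seeds:
            traj, _ = simulate_trajectory(prof, geometry, 90.0, 30.0, seed=seed)
            vals.append(position_features_er(traj, geometry)["time_center"])
        return np.mean(vals)

    assert center_time(0.9) < center_time(0.5) < center_time(0.1)
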