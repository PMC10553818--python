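"""Trajectory smoothing, heading series, classification and reversal logic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from optoguide.errors import InvalidArgumentError, UndefinedHeadingError
from optoguide.kinematics import (
    HeadingSeries,
    Track,
    alignment_cosine,
    angular_velocity,
    classify_two_spot,
    detect_reversal,
    heading_series,
    normalize_track_frame,
    smooth_track,
    wrap_angle,
)
from optoguide.synthetic import SyntheticCellSpec, make_trajectory


def brute_force_unwrap(angles):
    """Greedy ±2π correction oracle: each angle is shifted by the multiple
    of 2π that brings it within π of its predecessor."""
    out = [angles[0]]
    for a in angles[1:]:
        while a - out[-1] > np.pi:
            a -= 2 * np.pi
        while a - out[-1] < -np.pi:
            a += 2 * np.pi
        out.append(a)
    return np.array(out)


def track_from_xy(x, y, dt=5.0, cell_id="t"):
    t = np.arange(len(x)) * dt
    return Track(cell_id, t, np.asarray(x, float), np.asarray(y, float))


class TestSmoothTrack:
    def test_cubic_trajectory_reproduced_exactly(self):
        t = np.arange(20) * 5.0
        x = 1e-4 * t**3 - 0.01 * t**2 + 0.5 * t
        y = -2e-4 * t**3 + 0.2 * t - 3.0
        tr = smooth_track(track_from_xy(x, y))
        np.testing.assert_allclose(tr.x_um, x, atol=1e-9)
        np.testing.assert_allclose(tr.y_um, y, atol=1e-9)

    def test_noise_reduction_matches_filter_gain_oracle(self):
        # white-noise SD is scaled by sqrt(sum of squared filter weights):
        # exactly 0.5054 for window 9, order 3 (a 1.98x reduction)
        from scipy.signal import savgol_coeffs

        expected_ratio = np.sqrt((savgol_coeffs(9, 3) ** 2).sum())
        rng = np.random.default_rng(5)
        t = np.arange(2000) * 5.0
        x = 0.1 * t
        noisy = x + rng.normal(0, 0.5, len(t))
        smoothed = smooth_track(track_from_xy(noisy, np.zeros_like(t)))
        interior = slice(4, -4)
        ratio = np.std(smoothed.x_um[interior] - x[interior]) / np.std(
            noisy[interior] - x[interior]
        )
        assert ratio == pytest.approx(expected_ratio, rel=0.05)

    def test_short_track_rejected(self):
        with pytest.raises(InvalidArgumentError):
            smooth_track(track_from_xy(np.arange(8.0), np.zeros(8)))


class TestHeadingSeries:
    def test_constant_velocity_all_confident(self):
        # 10 um/min at 45 degrees
        v = 10.0 / 60.0
        t = np.arange(20) * 5.0
        x = v * t * np.cos(np.pi / 4)
        y = v * t * np.sin(np.pi / 4)
        hs = heading_series(track_from_xy(x, y))
        assert hs.confident.all()
        np.testing.assert_allclose(hs.angle_rad, np.pi / 4, atol=1e-12)

    def test_pause_carries_last_confident_angle(self):
        v = 10.0 / 60.0
        dt = 5.0
        x = list(np.arange(10) * v * dt)  # moving east
        x += [x[-1]] * 5  # 5-frame pause (0 um/min)
        x += list(x[-1] + np.arange(1, 8) * v * dt)
        x = np.array(x)
        hs = heading_series(track_from_xy(x, np.zeros_like(x)))
        pause_steps = slice(9, 14)
        assert not hs.confident[pause_steps].any()
        np.testing.assert_allclose(hs.angle_rad[pause_steps], 0.0, atol=1e-12)

    def test_full_circle_unwraps_to_2pi(self):
        spec = SyntheticCellSpec(mode="turn", turn_rpm=1.0, speed_um_min=20.0)
        track, _ = make_trajectory(spec, duration_s=60.0, dt_s=1.0)
        hs = heading_series(track)
        # step headings are chord directions sampled at mid-steps, so the
        # series spans (n_steps - 1) steps of the 1 rpm rotation
        expected = 2 * np.pi * 59.0 / 60.0
        assert hs.angle_rad[-1] - hs.angle_rad[0] == pytest.approx(expected, abs=1e-6)
        assert hs.angle_rad[-1] - hs.angle_rad[0] > np.pi  # genuinely unwrapped

    def test_unwrap_matches_brute_force_oracle_on_random_walks(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(5, 40)
            angles = rng.uniform(-np.pi, np.pi, n)
            steps = 5.0 * np.column_stack([np.cos(angles), np.sin(angles)])
            pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            hs = heading_series(track_from_xy(pos[:, 0], pos[:, 1], dt=5.0))
            oracle = brute_force_unwrap(angles)
            np.testing.assert_allclose(hs.angle_rad, oracle, atol=1e-9)

    def test_never_confident_track_flagged(self):
        x = np.arange(10) * 0.001  # ~0.01 um/min
        hs = heading_series(track_from_xy(x, np.zeros_like(x)))
        assert hs.n_confident == 0
        assert np.isnan(hs.angle_rad).all()


class TestClassifyTwoSpot:
    AXES = [(1.0, 0.0), (-1.0, 0.0)]

    def test_frontward_by_20um_rule(self):
        x = np.linspace(0, 25, 15)
        y = np.linspace(0, -5, 15)
        assert classify_two_spot(track_from_xy(x, y), self.AXES) == "frontward"

    def test_zero_displacement_is_nonresponder(self):
        x = np.zeros(15)
        assert classify_two_spot(track_from_xy(x, x), self.AXES) == "nonresponder"

    def test_rearward(self):
        x = np.linspace(0, -30, 15)
        assert classify_two_spot(track_from_xy(x, x * 0), self.AXES) == "rearward"

    def test_zero_axis_rejected(self):
        with pytest.raises(InvalidArgumentError):
            classify_two_spot(track_from_xy(np.arange(5.0), np.zeros(5)), [(0, 0), (1, 0)])

    @given(
        final=st.tuples(
            st.floats(-60, 60, allow_nan=False), st.floats(-60, 60, allow_nan=False)
        ),
        thresholds=st.lists(
            st.floats(5, 60, allow_nan=False), min_size=2, max_size=2, unique=True
        ),
    )
    def test_threshold_monotonicity(self, final, thresholds):
        # raising the threshold never converts a nonresponder into a responder
        lo, hi = sorted(thresholds)
        x = np.linspace(0, final[0], 15)
        y = np.linspace(0, final[1], 15)
        track = track_from_xy(x, y)
        at_lo = classify_two_spot(track, self.AXES, threshold_um=lo)
        at_hi = classify_two_spot(track, self.AXES, threshold_um=hi)
        if at_lo == "nonresponder":
            assert at_hi == "nonresponder"


def heading_from_angles(angles, dt=5.0):
    t = (np.arange(len(angles)) + 1) * dt
    return HeadingSeries(
        t_s=t, angle_rad=np.asarray(angles, float), confident=np.ones(len(angles), bool)
    )


class TestDetectReversal:
    STIMS = [np.pi / 2, -np.pi / 2]

    def test_dwell_at_both_stimuli_in_one_epoch_is_reverser(self):
        angles = [np.pi / 2] * 12 + [-np.pi / 2] * 12
        hs = heading_from_angles(angles)
        assert detect_reversal(hs, self.STIMS, epochs=[(0.0, 150.0)]) is True

    def test_dwell_at_one_stimulus_only_is_not(self):
        hs = heading_from_angles([np.pi / 2] * 24)
        assert detect_reversal(hs, self.STIMS, epochs=[(0.0, 150.0)]) is False

    def test_dwells_in_different_epochs_do_not_count(self):
        angles = [np.pi / 2] * 12 + [-np.pi / 2] * 12
        hs = heading_from_angles(angles)  # t in [5, 120]
        epochs = [(0.0, 60.0), (60.1, 150.0)]
        assert detect_reversal(hs, self.STIMS, epochs=epochs) is False

    def test_overlapping_epochs_rejected(self):
        hs = heading_from_angles([0.0] * 10)
        with pytest.raises(InvalidArgumentError):
            detect_reversal(hs, self.STIMS, epochs=[(0, 50), (40, 80)])

    def test_alignment_judged_on_wrapped_distance(self):
        # unwrapped angle 5pi/2 is aligned with stimulus at pi/2
        angles = [np.pi / 2] * 5 + list(np.linspace(np.pi / 2, 5 * np.pi / 2, 14))
        hs = heading_from_angles(angles)
        stims = [np.pi / 2, np.pi / 2 + np.pi]
        assert detect_reversal(hs, stims, epochs=[(0.0, 150.0)]) is True

    def test_perfect_sensitivity_and_specificity_on_planted_cohorts(self):
        # noiseless planted reversers and persistent non-reversers
        epochs = [(0.0, 300.0)]
        for seed in range(10):
            h0 = seed * 0.6 - 3.0
            stims = [h0, h0 + np.pi]
            spec = SyntheticCellSpec(mode="reverser", heading0_rad=h0, switch_time_s=150.0)
            track, _ = make_trajectory(spec, 300.0, 5.0)
            assert detect_reversal(heading_series(track), stims, epochs) is True
            spec_p = SyntheticCellSpec(mode="persistent", heading0_rad=h0)
            track_p, _ = make_trajectory(spec_p, 300.0, 5.0)
            assert detect_reversal(heading_series(track_p), stims, epochs) is False


class TestAngularVelocity:
    def test_closed_form_one_rpm(self):
        t = (np.arange(30) + 1) * 2.0
        hs = HeadingSeries(t, 2 * np.pi * t / 60.0, np.ones(30, bool))
        assert angular_velocity(hs, (0, 60)) == pytest.approx(1.0, abs=1e-12)

    def test_constant_heading_zero_rpm(self):
        hs = heading_from_angles([0.7] * 20)
        assert angular_velocity(hs, (0, 100)) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_planted_rpm_within_3se(self):
        rng = np.random.default_rng(9)
        t = (np.arange(60) + 1) * 2.0
        omega = 0.5 * 2 * np.pi / 60.0  # 0.5 rpm in rad/s
        noise_sd = 0.1
        angles = omega * t + rng.normal(0, noise_sd, len(t))
        hs = HeadingSeries(t, angles, np.ones(len(t), bool))
        est = angular_velocity(hs, (0, 120))
        # LS slope SE oracle
        se_slope = noise_sd / np.sqrt(np.sum((t - t.mean()) ** 2))
        se_rpm = se_slope * 60 / (2 * np.pi)
        assert abs(est - 0.5) < 3 * se_rpm

    def test_offset_invariance_and_time_shift_equivariance(self):
        t = (np.arange(30) + 1) * 2.0
        angles = 0.01 * t + 0.3 * np.sin(t / 7)
        hs = HeadingSeries(t, angles, np.ones(30, bool))
        w1 = angular_velocity(hs, (0, 60))
        hs2 = HeadingSeries(t, angles + 17.0, np.ones(30, bool))
        assert angular_velocity(hs2, (0, 60)) == pytest.approx(w1, abs=1e-12)
        hs3 = HeadingSeries(t + 100.0, angles, np.ones(30, bool))
        assert angular_velocity(hs3, (100, 160)) == pytest.approx(w1, abs=1e-10)

    def test_too_few_points_rejected(self):
        hs = heading_from_angles([0.0] * 20)
        with pytest.raises(InvalidArgumentError):
            angular_velocity(hs, (0, 7))


class TestAlignmentCosine:
    @pytest.mark.parametrize(
        "offset,expected",
        [(0.0, 1.0), (np.pi, -1.0), (np.pi / 2, 0.0)],
        ids=["aligned", "opposed", "orthogonal"],
    )
    def test_closed_forms(self, offset, expected):
        hs = heading_from_angles([1.0] * 10)
        cos = alignment_cosine(hs, 1.0 - offset)
        np.testing.assert_allclose(cos, expected, atol=1e-12)


class TestNormalizeTrackFrame:
    def test_eastbound_track_maps_to_north(self):
        t = np.arange(30) * 5.0
        track = Track("e", t, 0.2 * t, np.zeros_like(t))
        norm = normalize_track_frame(track)
        # displacement after the 1-minute mark heads +y
        assert norm.y_um[-1] > 0
        np.testing.assert_allclose(norm.x_um, 0.0, atol=1e-9)
        # the 1-minute-mark position is the origin
        i1 = int(np.nonzero(t <= 60.0)[0][-1])
        assert norm.x_um[i1] == pytest.approx(0.0, abs=1e-9)
        assert norm.y_um[i1] == pytest.approx(0.0, abs=1e-9)

    def test_idempotent_on_normalized_input(self):
        t = np.arange(30) * 5.0
        track = Track("e", t, 0.2 * t, 0.05 * t)
        once = normalize_track_frame(track)
        twice = normalize_track_frame(once)
        np.testing.assert_allclose(twice.x_um, once.x_um, atol=1e-9)
        np.testing.assert_allclose(twice.y_um, once.y_um, atol=1e-9)

    def test_mirrored_inputs_give_mirrored_outputs(self):
        t = np.arange(30) * 5.0
        y = 0.2 * t
        x = 0.05 * np.sin(t / 20)
        a = normalize_track_frame(Track("a", t, x, y))
        b = normalize_track_frame(Track("b", t, -x, y))
        np.testing.assert_allclose(a.x_um, -b.x_um, atol=1e-9)
        np.testing.assert_allclose(a.y_um, b.y_um, atol=1e-9)

    def test_zero_initial_displacement_rejected(self):
        t = np.arange(30) * 5.0
        x = np.where(t <= 60, 0.0, t - 60)
        with pytest.raises(UndefinedHeadingError):
            normalize_track_frame(Track("z", t, x * 0, x * 0))


@given(st.floats(-20, 20, allow_nan=False))
def test_wrap_angle_in_range_and_consistent(a):
    w = wrap_angle(a)
    assert -np.pi < w <= np.pi
    assert np.cos(w) == pytest.approx(np.cos(a), abs=1e-9)
    assert np.sin(w) == pytest.approx(np.sin(a), abs=1e-9)
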