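"""Synthetic generators: trajectories, movies, adaptive circuit, virtual assays."""

import numpy as np
import pytest

from optoguide.errors import InvalidArgumentError, OutOfFieldError
from optoguide.image_prep import fit_background, segment_cell
from optoguide.kinematics import (
    angular_velocity,
    detect_reversal,
    heading_series,
    wrap_angle,
)
from optoguide.peripheral import angular_profile, ring_mask
from optoguide.stimulus import ProtocolPhase, SpotSpec, StimulusProtocol
from optoguide.synthetic import (
    AdaptiveResponseSpec,
    BackgroundSpec,
    ControllerRules,
    GuidanceCellModel,
    SyntheticCellSpec,
    make_cell_movie,
    make_trajectory,
    run_virtual_assay,
    simulate_adaptive_response,
)


class TestMakeTrajectory:
    def test_persistent_noiseless_straight_line(self):
        spec = SyntheticCellSpec(speed_um_min=10.0, heading0_rad=np.pi / 6)
        track, headings = make_trajectory(spec, duration_s=300.0, dt_s=5.0)
        assert len(track) == 61
        net = np.hypot(track.x_um[-1], track.y_um[-1])
        assert net == pytest.approx(50.0, rel=1e-9)
        assert np.arctan2(track.y_um[-1], track.x_um[-1]) == pytest.approx(np.pi / 6)
        np.testing.assert_allclose(headings, np.pi / 6)

    def test_turner_recovered_at_planted_rpm(self):
        spec = SyntheticCellSpec(mode="turn", turn_rpm=0.5, speed_um_min=10.0)
        track, _ = make_trajectory(spec, duration_s=300.0, dt_s=5.0)
        hs = heading_series(track)
        est = angular_velocity(hs, (0.0, 300.0))
        assert est == pytest.approx(0.5, rel=0.02)

    def test_reverser_flagged_by_detector(self):
        spec = SyntheticCellSpec(mode="reverser", switch_time_s=150.0)
        track, _ = make_trajectory(spec, duration_s=300.0, dt_s=5.0)
        hs = heading_series(track)
        assert detect_reversal(hs, [0.0, np.pi], epochs=[(0.0, 300.0)]) is True

    def test_reproducibility_bit_identical(self):
        spec = SyntheticCellSpec(mode="turn", turn_rpm=0.3)
        a, ha = make_trajectory(spec, 200.0, 5.0, noise_sd_um=0.5, seed=7)
        b, hb = make_trajectory(spec, 200.0, 5.0, noise_sd_um=0.5, seed=7)
        np.testing.assert_array_equal(a.x_um, b.x_um)
        np.testing.assert_array_equal(a.y_um, b.y_um)
        np.testing.assert_array_equal(ha, hb)

    def test_invalid_durations_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_trajectory(SyntheticCellSpec(), duration_s=0.0, dt_s=5.0)
        with pytest.raises(InvalidArgumentError):
            make_trajectory(SyntheticCellSpec(), duration_s=10.0, dt_s=-1.0)


class TestMakeCellMovie:
    def test_stationary_disk_perfect_segmentation(self):
        cell = SyntheticCellSpec(mode="stationary", radius_um=8.0)
        bg = BackgroundSpec(coefficients=(0.0, 0.0, 50.0))
        movie, truth = make_cell_movie(cell, bg, duration_s=20.0, dt_s=5.0)
        cm = segment_cell(movie.channel("PHAkt")[0])
        iou = (cm.mask & truth.masks[0]).sum() / (cm.mask | truth.masks[0]).sum()
        assert iou == pytest.approx(1.0, abs=0.02)

    def test_planted_plane_recovered_to_1e6(self):
        cell = SyntheticCellSpec(mode="stationary")
        bg = BackgroundSpec(coefficients=(0.5, -0.2, 10.0))
        movie, truth = make_cell_movie(cell, bg, duration_s=10.0, dt_s=5.0)
        frame = movie.channel("PHAkt")[0]
        fit = fit_background(frame, ~truth.masks[0], "plane")
        np.testing.assert_allclose(fit.coefficients, [0.5, -0.2, 10.0], atol=1e-6)

    def test_polarized_cell_peripheral_argmax_at_heading(self):
        cell = SyntheticCellSpec(
            mode="stationary", polarity_kappa=2.0, heading0_rad=np.radians(30.0),
            radius_um=10.0,
        )
        bg = BackgroundSpec(coefficients=(0.0, 0.0, 10.0))
        movie, truth = make_cell_movie(cell, bg, duration_s=10.0, dt_s=5.0)
        corrected = movie.channel("PHAkt")[0] - truth.background
        ring = ring_mask(truth.masks[0], 14)
        prof = angular_profile(corrected, ring, tuple(truth.centroids_px[0]))
        peak_deg = prof.bin_centers_deg[np.nanargmax(prof.mean_intensity)]
        assert abs(peak_deg - 30.0) <= 5.0

    def test_cell_leaving_field_names_first_frame(self):
        cell = SyntheticCellSpec(speed_um_min=60.0)  # 1 um/s eastward
        bg = BackgroundSpec()
        with pytest.raises(OutOfFieldError) as err:
            make_cell_movie(cell, bg, field_px=120, duration_s=300.0, dt_s=5.0)
        assert err.value.frame_index > 0

    def test_reproducibility(self):
        cell = SyntheticCellSpec(mode="stationary")
        bg = BackgroundSpec(noise_sd=3.0)
        m1, _ = make_cell_movie(cell, bg, duration_s=10.0, dt_s=5.0, seed=3)
        m2, _ = make_cell_movie(cell, bg, duration_s=10.0, dt_s=5.0, seed=3)
        np.testing.assert_array_equal(m1.channel("PHAkt"), m2.channel("PHAkt"))


class TestAdaptiveResponse:
    DT = 1.0

    def step_input(self, n=601):
        p = np.ones(n)
        p[0] = 0.0
        return p

    def test_step_overshoot_then_decline(self):
        r = simulate_adaptive_response(self.step_input(), AdaptiveResponseSpec(), self.DT)
        peak = r.max()
        plateau = r[-60:].mean()
        assert peak > 1.5 * plateau
        assert r.argmax() < len(r) - 100  # the decline happens within the trace

    def test_slow_ramp_attenuated_versus_step(self):
        spec = AdaptiveResponseSpec()
        step_peak = simulate_adaptive_response(self.step_input(), spec, self.DT).max()
        t = np.arange(601) * self.DT
        ramp = np.clip(t / 300.0, 0.0, 1.0)
        ramp_peak = simulate_adaptive_response(ramp, spec, self.DT).max()
        assert ramp_peak < 0.5 * step_peak

    def test_feedback_off_monotone(self):
        spec = AdaptiveResponseSpec(feedback_strength=0.0)
        r = simulate_adaptive_response(self.step_input(), spec, self.DT)
        assert np.all(np.diff(r) >= -1e-12)

    def test_feedback_strength_interpolates_peak_ratio(self):
        ratios = []
        for fs in (1.0, 0.5, 0.1):
            spec = AdaptiveResponseSpec(feedback_strength=fs)
            r = simulate_adaptive_response(self.step_input(2001), spec, self.DT)
            ratios.append(r.max() / r[-100:].mean())
        assert ratios[0] > ratios[1] > ratios[2]

    def test_negative_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_adaptive_response([0.0, -1.0], AdaptiveResponseSpec(), 1.0)


def two_spot_protocol(a1=90.0, a2=-90.0, duration=300.0, frame="initial_heading"):
    return StimulusProtocol(
        phases=[
            ProtocolPhase(
                duration_s=duration,
                pattern="spots",
                spots=[SpotSpec(angle_deg=a1, frame=frame), SpotSpec(angle_deg=a2, frame=frame)],
            )
        ]
    )


class TestVirtualAssay:
    RULES = ControllerRules()
    MODEL = GuidanceCellModel()

    def final_alignment(self, result):
        h = result.headings_rad
        t = result.t_control_s
        h0 = h[np.argmin(np.abs(t - self.RULES.pretrack_s))]
        last = t >= t[-1] - 60.0
        return [
            float(np.abs(wrap_angle(h[last] - (h0 + a))).max())
            for a in (np.pi / 2, -np.pi / 2)
        ]

    def test_winner_take_all_at_pm90(self):
        for seed in range(3):
            res = run_virtual_assay(self.MODEL, self.RULES, two_spot_protocol(), seed=seed)
            devs = self.final_alignment(res)
            aligned = [d <= 0.4 for d in devs]
            assert sum(aligned) == 1, f"seed {seed}: {np.degrees(devs)}"

    def test_front_back_stimuli_preserve_direction(self):
        proto = two_spot_protocol(a1=0.0, a2=180.0)
        res = run_virtual_assay(self.MODEL, self.RULES, proto, seed=0)
        h = res.headings_rad
        t = res.t_control_s
        h0 = h[np.argmin(np.abs(t - self.RULES.pretrack_s))]
        assert abs(h[-1] - h0) < np.radians(30.0)

    def test_local_then_global_flips_angular_velocity(self):
        proto = StimulusProtocol(
            phases=[
                ProtocolPhase(
                    duration_s=180.0, pattern="spots",
                    spots=[SpotSpec(angle_deg=90.0, frame="heading")],
                ),
                ProtocolPhase(duration_s=180.0, pattern="global"),
            ]
        )
        res = run_virtual_assay(self.MODEL, self.RULES, proto, seed=0)
        hs = heading_series(res.track)
        t_switch = self.RULES.pretrack_s + 180.0
        w_local = angular_velocity(hs, (t_switch - 120.0, t_switch))
        w_global = angular_velocity(hs, (t_switch, t_switch + 120.0))
        assert w_local > 0  # left stimulation turns counterclockwise
        assert w_global < 0  # global switch reverses the turning

    def test_per_side_initial_rates_swap_after_switch(self):
        proto = StimulusProtocol(
            phases=[
                ProtocolPhase(
                    duration_s=180.0, pattern="spots",
                    spots=[SpotSpec(angle_deg=90.0, frame="heading")],
                ),
                ProtocolPhase(duration_s=180.0, pattern="global"),
            ]
        )
        res = run_virtual_assay(self.MODEL, self.RULES, proto, seed=1)
        t = res.t_control_s

        def rate(trace, t0):
            sel = (t >= t0) & (t <= t0 + 30.0)
            return np.polyfit(t[sel], trace[sel], 1)[0]

        t_stim, t_switch = self.RULES.pretrack_s, self.RULES.pretrack_s + 180.0
        assert rate(res.left_P, t_stim) > rate(res.right_P, t_stim)
        assert rate(res.right_P, t_switch) > rate(res.left_P, t_switch)

    def test_event_log_and_reproducibility(self):
        res1 = run_virtual_assay(self.MODEL, self.RULES, two_spot_protocol(), seed=5)
        res2 = run_virtual_assay(self.MODEL, self.RULES, two_spot_protocol(), seed=5)
        np.testing.assert_array_equal(res1.track.x_um, res2.track.x_um)
        np.testing.assert_array_equal(res1.headings_rad, res2.headings_rad)
        assert len(res1.event_log) > 0
        assert res1.event_log[0]["pattern"] == "spot"

    def test_heading_frame_without_pretrack_rejected(self):
        rules = ControllerRules(pretrack_s=0.0)
        from optoguide.errors import UndefinedHeadingError

        with pytest.raises(UndefinedHeadingError):
            run_virtual_assay(self.MODEL, rules, two_spot_protocol(), seed=0)

    def test_lab_frame_without_pretrack_allowed(self):
        rules = ControllerRules(pretrack_s=0.0)
        proto = two_spot_protocol(frame="lab", duration=60.0)
        res = run_virtual_assay(self.MODEL, rules, proto, seed=0)
        assert len(res.track) > 0

    def test_rendered_movie_ground_truth(self):
        proto = two_spot_protocol(duration=120.0)
        res = run_virtual_assay(
            self.MODEL, self.RULES, proto, seed=2, render_movie=True
        )
        assert res.movie is not None
        assert res.movie.n_frames == res.ground_truth.masks.shape[0]
        # the cell never leaves the rendered field
        assert res.ground_truth.masks.any(axis=(1, 2)).all()
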