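"""Kinetics estimators: expansion, closure rate, onset detection."""

import numpy as np
import pytest

from woundrepair.dynamics import (
    DidNotCloseError,
    contraction_rate,
    detect_onset,
    fold_expansion,
    summarize_dynamics,
)
from woundrepair.geometry import WoundTrajectory
from woundrepair.io import TimeLapseStack
from woundrepair.simulate import WoundSimConfig, simulate_stack

from conftest import SHORT_TIMES


def trajectory_from_areas(areas, times=None):
    areas = np.asarray(areas, dtype=float)
    t = np.asarray(times, float) if times is not None else np.arange(len(areas)) * 30.0
    masks = np.zeros((len(areas), 4, 4), bool)
    return WoundTrajectory(t, areas, np.full((len(areas), 2), 2.0), masks, 0.22)


class TestFoldExpansion:
    def test_arithmetic(self):
        traj = trajectory_from_areas([254.5, 440.0, 420.0, 200.0])
        assert fold_expansion(traj) == pytest.approx(440.0 / 254.5)

    def test_monotone_decreasing_gives_one(self):
        assert fold_expansion(trajectory_from_areas([300, 200, 100])) == 1.0

    def test_zero_initial_area_rejected(self):
        with pytest.raises(ValueError):
            fold_expansion(trajectory_from_areas([0.0, 10.0, 5.0]))


class TestContractionRate:
    def test_two_point_arithmetic(self):
        # max 440 μm² at 90 s; first frame at ≤ half is 220 μm² at 300 s
        areas = [254.5, 350, 400, 440, 430, 400, 350, 300, 250, 230, 220]
        traj = trajectory_from_areas(areas)  # 30-s frames: t_max=90, t_half=300
        cr = contraction_rate(traj)
        assert cr.t_max == 90.0 and cr.t_half == 300.0
        assert cr.rate == pytest.approx((440 - 220) / (300 - 90))
        assert not cr.band_undershoot

    def test_linear_contraction_recovered_exactly(self):
        # two-point estimator is exact on a piecewise-linear trajectory,
        # independent of frame quantization
        cfg = WoundSimConfig(contraction_rate=7.15, frame_times=SHORT_TIMES)
        areas = np.asarray(cfg.area_at(SHORT_TIMES))
        cr = contraction_rate(trajectory_from_areas(areas, SHORT_TIMES))
        assert cr.rate == pytest.approx(7.15, rel=1e-12)

    def test_band_undershoot_warning_below_35pct(self):
        cr = contraction_rate(trajectory_from_areas([100, 400, 300, 100]))
        assert cr.t_half == 90.0
        assert cr.band_undershoot  # 100 < 0.35·400

    def test_never_half_raises(self):
        with pytest.raises(DidNotCloseError):
            contraction_rate(trajectory_from_areas([100, 400, 390, 380]))

    def test_time_shift_invariance(self):
        areas = [254.5, 440, 300, 150, 60]
        a = contraction_rate(trajectory_from_areas(areas))
        b = contraction_rate(
            trajectory_from_areas(areas, np.arange(5) * 30.0 + 1000.0)
        )
        assert a.rate == b.rate
        assert fold_expansion(trajectory_from_areas(areas)) == pytest.approx(
            440 / 254.5
        )


class TestDetectOnset:
    def make_stack(self, onset_frame=None, t=8, size=128, level=100.0, bump=60.0):
        frames = np.full((1, t, size, size), level)
        c = (size - 1) / 2
        rr = np.hypot(*np.meshgrid(*[np.arange(size) - c] * 2, indexing="ij")) * 0.22
        if onset_frame is not None:
            for i in range(onset_frame, t):
                frames[0, i][(rr >= 9.0) & (rr < 13.0)] += bump
        stack = TimeLapseStack(frames, ["rep"], np.arange(t) * 30.0, 0.22)
        masks = np.stack([rr < 9.0] * t)
        from woundrepair.geometry import accept_masks

        return stack, accept_masks(stack, masks)

    def test_background_only_channel_not_recruited(self):
        stack, traj = self.make_stack(onset_frame=None)
        assert detect_onset(stack, traj, "rep") is None

    def test_noiseless_step_at_60s_detected_exactly(self):
        stack, traj = self.make_stack(onset_frame=2)
        assert detect_onset(stack, traj, "rep") == 60.0

    def test_single_flagged_frame_is_not_an_onset(self):
        stack, traj = self.make_stack(onset_frame=7)  # last frame only
        assert detect_onset(stack, traj, "rep") is None

    def test_frame_count_mismatch_rejected(self):
        stack, traj = self.make_stack(onset_frame=2)
        short = TimeLapseStack(
            stack.frames[:, :4], ["rep"], stack.frame_times[:4], 0.22
        )
        with pytest.raises(ValueError):
            detect_onset(short, traj, "rep")

    def test_actin_onset_on_simulated_control(self, control_sim, control_traj):
        onset = detect_onset(control_sim.stack, control_traj, "actin")
        assert onset == control_sim.manifest.onsets["actin"]


class TestSummary:
    def test_summary_fields_consistent(self, control_sim, control_traj):
        s = summarize_dynamics(control_traj, control_sim.stack)
        assert s.fold_expansion == pytest.approx(s.a_max / s.a0)
        assert s.t_half > s.t_max
        assert s.contraction_rate > 0
        assert s.onsets["actin"] == 60.0
        d = s.to_dict()
        assert d["onset_actin"] == 60.0

    def test_noiseless_scar_onset_ensemble_means_33s(self):
        # 9 embryos recruiting at the 30-s frame and 1 at the 60-s frame
        # under 30-s sampling average to a 33-s onset
        onsets = []
        for i in range(3):  # sub-sample of the ensemble; full set in acceptance
            true_onset = 30.0 if i < 2 else 60.0
            cfg = WoundSimConfig(
                frame_times=np.arange(0.0, 301.0, 30.0),
                reporter_onsets={"scar": true_onset},
                noise_sigma=0.0,
                seed=i,
            )
            sim = simulate_stack(cfg)
            from woundrepair.geometry import segment_wound

            traj = segment_wound(sim.stack)
            onsets.append(detect_onset(sim.stack, traj, "scar"))
        assert onsets == [30.0, 30.0, 60.0]
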