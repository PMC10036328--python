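"""Forward-model contracts: trajectory, rendering, presets, determinism."""

import numpy as np
import pytest

from woundrepair.profiles import fold_profile, radial_lineplot
from woundrepair.simulate import (
    WoundSimConfig,
    default_frame_times,
    embryo_seed,
    preset,
    preset_names,
    simulate_stack,
)

from conftest import SHORT_TIMES, short_preset


class TestTrajectory:
    def test_max_area_is_expansion_fold_times_initial(self):
        cfg = WoundSimConfig(
            initial_area=100.0, expansion_fold=2.0, frame_times=SHORT_TIMES
        )
        assert cfg.area_at(cfg.t_max) == pytest.approx(200.0)
        sim = simulate_stack(
            WoundSimConfig(
                initial_area=100.0,
                expansion_fold=2.0,
                frame_times=SHORT_TIMES,
                noise_sigma=0.0,
            )
        )
        assert sim.manifest.areas.max() == pytest.approx(200.0)

    def test_piecewise_linear_rise_and_fall(self):
        cfg = WoundSimConfig(frame_times=SHORT_TIMES)
        t = np.linspace(0, 300, 301)
        a = np.asarray(cfg.area_at(t))
        i_max = int(np.argmax(t >= cfg.t_max))
        assert np.all(np.diff(a[: i_max + 1]) >= 0)
        assert np.all(np.diff(a[i_max:]) <= 0)
        assert np.all(a >= 0)
        # slopes match the configured parameters exactly
        rise = (cfg.expansion_fold - 1) * cfg.initial_area / cfg.t_max
        assert a[1] - a[0] == pytest.approx(rise)
        assert a[100] - a[101] == pytest.approx(cfg.contraction_rate)
        assert a[-1] == 0.0  # floored after full closure

    @pytest.mark.parametrize(
        "bad",
        [
            dict(frame_times=np.array([0.0, 30.0, 30.0])),
            dict(frame_times=np.array([10.0, 40.0])),
            dict(expansion_fold=0.9),
            dict(contraction_rate=-1.0),
            dict(initial_area=-5.0),
            dict(ring_width_true=0.0),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            WoundSimConfig(**bad)


class TestRendering:
    def test_seed_determinism(self):
        a = simulate_stack(short_preset("control", seed=7))
        b = simulate_stack(short_preset("control", seed=7))
        np.testing.assert_array_equal(a.stack.frames, b.stack.frames)
        np.testing.assert_array_equal(a.unwounded, b.unwounded)
        c = simulate_stack(short_preset("control", seed=8))
        assert not np.array_equal(a.stack.frames, c.stack.frames)

    def test_noiseless_rendered_area_matches_manifest(self):
        cfg = short_preset("control", noise_sigma=0.0, speckle_contrast=0.0)
        sim = simulate_stack(cfg)
        px2 = cfg.pixel_size**2
        mid = cfg.background * (1 + cfg.wound_floor) / 2
        for i in range(8):
            true_area = sim.manifest.areas[i]
            if true_area == 0:
                continue
            rendered = (sim.stack.frames[0, i] < mid).sum() * px2
            # tolerance: one pixel-wide ring around the wound perimeter
            perim = 2 * np.pi * np.sqrt(true_area / np.pi) * cfg.pixel_size
            assert abs(rendered - true_area) <= perim + px2

    def test_ring_appears_only_after_onset(self, control_sim):
        man = control_sim.manifest
        frames = control_sim.stack.frames[0]
        t = control_sim.stack.frame_times
        onset = man.onsets["actin"]
        pre = frames[t < onset].max()
        post = frames[(t >= onset) & (t <= 120)].max()
        bg = 100.0
        assert pre < 1.8 * bg  # background + speckle + noise only
        assert post > 2.2 * bg  # bright ring present

    def test_disassembly_decays_ring(self, scar_sim):
        # ring peak amplitude drops after the disassembly time
        man = scar_sim.manifest
        stack = scar_sim.stack
        i_90 = stack.frame_index_at(90.0)
        i_late = stack.frame_index_at(330.0)

        def ring_peak(i):
            _, curve = fold_profile(
                radial_lineplot(stack.frames[0, i], man.center, pixel_size=0.22)
            )
            return np.nanmax(curve)

        assert ring_peak(i_late) < ring_peak(i_90) - 10.0

    def test_radial_symmetry_of_noiseless_render(self):
        cfg = short_preset("control", noise_sigma=0.0, speckle_contrast=0.0)
        sim = simulate_stack(cfg)
        frame = sim.stack.frames[0, sim.stack.frame_index_at(90.0)]
        center = sim.manifest.center
        base = radial_lineplot(frame, center, pixel_size=0.22).mean
        rotated = radial_lineplot(np.rot90(frame), center, pixel_size=0.22).mean
        ok = np.isfinite(base) & np.isfinite(rotated)
        np.testing.assert_allclose(base[ok], rotated[ok], rtol=1e-10)

    def test_manifest_ring_radii_track_wound_edge(self, control_sim):
        man = control_sim.manifest
        has_ring = np.isfinite(man.ring_inner_radii)
        r_wound = np.sqrt(man.areas[has_ring] / np.pi)
        np.testing.assert_allclose(
            man.ring_outer_radii[has_ring] - man.ring_inner_radii[has_ring],
            5.34,
        )
        assert np.all(man.ring_inner_radii[has_ring] > r_wound)

    def test_manifest_roundtrip(self, control_sim):
        from woundrepair.simulate import GroundTruthManifest

        d = control_sim.manifest.to_dict()
        back = GroundTruthManifest.from_dict(d)
        np.testing.assert_array_equal(back.areas, control_sim.manifest.areas)
        assert back.onsets == control_sim.manifest.onsets


class TestPresets:
    def test_preset_values_match_measured_conditions(self):
        assert preset("control").expansion_fold == pytest.approx(1.74)
        assert preset("control").ring_width_true == pytest.approx(5.34)
        assert preset("control").ring_rel_intensity_true == pytest.approx(2.43)
        assert preset("control").contraction_rate == pytest.approx(7.15)
        assert preset("scar_rnai").contraction_rate == pytest.approx(9.12)
        assert preset("scar_rnai").disassembly_time is not None
        assert preset("rac_inhibited").expansion_fold == pytest.approx(2.59)
        # Rac inhibition: no ring is formed (amplitude at background level)
        assert preset("rac_inhibited").ring_rel_intensity_true == pytest.approx(1.0)

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="control"):
            preset("nonsense")
        assert set(preset_names()) == {"control", "rac_inhibited", "scar_rnai"}

    def test_default_schedule_matches_acquisition(self):
        t = default_frame_times()
        assert t[0] == 0.0 and t[-1] == 1800.0
        assert np.all(np.diff(t[t <= 900]) == 30.0)
        assert np.all(np.diff(t[t >= 900]) == 60.0)


def test_embryo_seed_is_stable_and_bounded():
    seeds = [embryo_seed(1, i) for i in range(20)]
    assert len(set(seeds)) == 20
    assert all(0 <= s < 2**31 for s in seeds)
    assert seeds == [embryo_seed(1, i) for i in range(20)]
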