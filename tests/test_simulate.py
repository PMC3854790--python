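"""Ground-truth generator: analytic midlines, rendering, determinism."""

import numpy as np
import pytest

from spermbeat.errors import GeometryError, ParameterError
from spermbeat.geometry import unit
from spermbeat.simulate import (RenderParams, WaveformParams, build_midline,
                                analytic_cell_frame, simulate_flash_experiment,
                                simulate_freeswim_movie,
                                simulate_tethered_movie)


class TestBuildMidline:
    def test_straight_segment_when_no_curvature_and_no_wave(self):
        p = WaveformParams(static_curvature_per_um=0.0, wave_amplitude=0.0)
        ml = build_midline(p, 0.0)
        end = ml.points_um[-1]
        expected = np.asarray(p.anchor_xy_um) + p.flagellum_length_um * unit(
            p.base_angle_rad)
        assert np.allclose(end, expected, atol=1e-6)
        assert ml.total_arclength_um == pytest.approx(p.flagellum_length_um,
                                                      rel=0.01)

    @pytest.mark.parametrize("hook", [1, -1])
    @pytest.mark.parametrize("c", [0.005, 0.01])
    def test_pure_static_curvature_gives_circular_arc(self, c, hook):
        # closed form: radius 1/c arc; geometric curvature is -hook*kappa0
        p = WaveformParams(static_curvature_per_um=c, wave_amplitude=0.0,
                           hook_sign=hook)
        ml = build_midline(p, 0.0)
        k = -hook * c
        L = p.flagellum_length_um
        x0, y0 = p.anchor_xy_um
        expected = np.array([x0 + np.sin(k * L) / k,
                             y0 + (1 - np.cos(k * L)) / k])
        assert np.linalg.norm(ml.points_um[-1] - expected) < 0.01 * L

    def test_periodic_in_one_beat_cycle(self):
        p = WaveformParams(wave_amplitude=0.8, beat_frequency_hz=6.0)
        a = build_midline(p, 0.25)
        b = build_midline(p, 0.25 + 1.0 / 6.0)
        assert np.allclose(a.points_um, b.points_um, atol=1e-9)

    def test_integrator_converges_under_step_halving(self):
        p = WaveformParams(static_curvature_per_um=0.01)
        coarse = build_midline(p, 0.1, ds_um=0.1)
        fine = build_midline(p, 0.1, ds_um=0.05)
        assert np.linalg.norm(coarse.points_um[-1] - fine.points_um[-1]) < 0.1

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            WaveformParams(flagellum_length_um=-1)
        with pytest.raises(ParameterError):
            WaveformParams(hook_sign=0)
        with pytest.raises(ParameterError):
            WaveformParams(wave_amplitude=-0.1)


class TestGroundTruthIndex:
    def test_zero_curvature_symmetric_beat_has_zero_mean_index(self):
        # evaluate on analytic midlines directly (no rendering needed)
        from spermbeat.beat import asymmetry_index_frame
        wave = WaveformParams(static_curvature_per_um=0.0)
        cell = analytic_cell_frame(wave)
        idx = [asymmetry_index_frame(build_midline(wave, t), cell)
               for t in np.linspace(0, 1.0, 201)[:-1]]
        assert abs(np.mean(idx)) < 1e-3

    def test_index_oracle_is_monotone_in_static_curvature(self):
        from spermbeat.beat import asymmetry_index_frame
        means = []
        for c in [-0.01, -0.005, 0.0, 0.005, 0.01]:
            wave = WaveformParams(static_curvature_per_um=c)
            cell = analytic_cell_frame(wave)
            idx = [asymmetry_index_frame(build_midline(wave, t), cell)
                   for t in np.linspace(0, 1.0 / 6, 34)[:-1]]
            means.append(np.mean(idx))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestTetheredMovie:
    def test_static_cell_renders_identical_frames(self):
        wave = WaveformParams(static_curvature_per_um=0.0, wave_amplitude=0.0)
        stack, _ = simulate_tethered_movie(
            wave, RenderParams(noise_sd=0.0, seed=0), 0.05)
        assert all(np.array_equal(stack.frames[0], f) for f in stack.frames)

    def test_same_seed_is_bit_identical(self):
        wave = WaveformParams()
        r = RenderParams(noise_sd=20.0, seed=13)
        a, _ = simulate_tethered_movie(wave, r, 0.05)
        b, _ = simulate_tethered_movie(wave, r, 0.05)
        assert np.array_equal(a.frames, b.frames)

    def test_frame_count_and_frequency_metadata(self):
        wave = WaveformParams(beat_frequency_hz=6.0)
        stack, gt = simulate_tethered_movie(
            wave, RenderParams(fps=200.0, noise_sd=0.0, seed=0), 2.0)
        assert stack.n_frames == 400
        assert gt.true_frequency_hz == 6.0
        assert len(gt.midlines) == 400

    def test_cell_must_fit_in_image(self):
        wave = WaveformParams()
        with pytest.raises(GeometryError):
            simulate_tethered_movie(
                wave, RenderParams(image_shape=(48, 48), noise_sd=0.0,
                                   seed=0), 0.05)


class TestFreeswimMovie:
    def test_zero_speed_gives_zero_ground_truth_vsl(self):
        _, _, gt = simulate_freeswim_movie(
            0.0, WaveformParams(), RenderParams(noise_sd=0.0, seed=0), 0.1)
        assert gt.true_vsl_um_s == 0.0

    def test_world_displacement_matches_kinematics(self):
        _, _, gt = simulate_freeswim_movie(
            50.0, WaveformParams(), RenderParams(noise_sd=0.0, seed=0), 2.0,
            lateral_amplitude_um=0.0)
        d = np.linalg.norm(gt.head_world_um[-1] - gt.head_world_um[0])
        # last frame is at t = (n-1)/fps, not t = duration
        n = gt.head_world_um.shape[0]
        assert d == pytest.approx(50.0 * (n - 1) / 200.0, rel=1e-6)

    def test_perfect_stage_tracking_keeps_head_pixel_fixed(self):
        stack, log, _ = simulate_freeswim_movie(
            50.0, WaveformParams(wave_amplitude=0.0),
            RenderParams(noise_sd=0.0, seed=0), 0.2,
            stage_follows=True, lateral_amplitude_um=0.0)
        assert all(np.array_equal(stack.frames[0], f) for f in stack.frames)
        assert np.hypot(log.x_um[-1], log.y_um[-1]) > 0


class TestFlashExperiment:
    def test_identical_phases_give_equal_indices(self):
        # flash placed so each phase spans an integer number of beat
        # cycles (the windowed index of a partial cycle is phase-biased)
        w = WaveformParams(static_curvature_per_um=0.005,
                           beat_frequency_hz=6.0)
        _, gt, _ = simulate_flash_experiment(
            w, w, RenderParams(fps=60.0, noise_sd=0.0, seed=0), 30, 1.0)
        assert gt.pre_index == pytest.approx(gt.post_index, abs=0.02)

    def test_lower_post_curvature_lowers_post_index(self):
        pre = WaveformParams(static_curvature_per_um=0.008)
        post = WaveformParams(static_curvature_per_um=0.002)
        _, gt, _ = simulate_flash_experiment(
            pre, post, RenderParams(fps=50.0, noise_sd=0.0, seed=0), 12, 0.5)
        assert gt.post_index < gt.pre_index

    @pytest.mark.parametrize("flash", [0, 24, 100])
    def test_flash_frame_must_be_strictly_inside(self, flash):
        w = WaveformParams()
        with pytest.raises(ParameterError):
            simulate_flash_experiment(
                w, w, RenderParams(fps=50.0, noise_sd=0.0, seed=0), flash, 0.5)

    def test_fluorescence_steps_down_at_flash(self):
        w = WaveformParams()
        _, _, trace = simulate_flash_experiment(
            w, w, RenderParams(fps=50.0, noise_sd=0.0, seed=0), 12, 0.5,
            trace_noise_sd=0.0)
        assert trace.raw[:12].mean() > trace.raw[12:].mean()
        assert trace.event_frame == 12
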