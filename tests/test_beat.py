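"""Asymmetry index, windowing, frequency/amplitude, flash, envelope."""

import numpy as np
import pytest

from spermbeat.beat import (align_envelope, asymmetry_index_frame,
                            beat_amplitude, beat_frequency, flash_response,
                            window_average, window_indices)
from spermbeat.errors import (AlignmentError, MissingValueError,
                              UndefinedIndexError)
from spermbeat.geometry import CellFrame, FlagellumTrace


def straight_cell(hook=1):
    """Horizontal cell: head centroid at origin, neck 4 µm along +x."""
    return CellFrame(head_centroid_um=np.array([0.0, 0.0]),
                     head_axis_angle_rad=0.0, hook_sign=hook,
                     neck_point_um=np.array([4.0, 0.0]),
                     neck_azimuth_rad=0.0)


def straight_trace(length=100.0, n=101):
    x = np.linspace(4.0, 4.0 + length, n)
    return FlagellumTrace(np.column_stack([x, np.zeros(n)]))


class TestAsymmetryIndex:
    def test_straight_flagellum_along_axis_is_zero(self):
        assert asymmetry_index_frame(straight_trace(), straight_cell()) == \
            pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("hook", [1, -1])
    def test_rigid_rotation_about_head_recovers_angle(self, hook):
        # closed-form oracle: rotate the midline rigidly about the head
        # centroid by 0.30 rad toward the anti-hook side -> index +0.30
        theta = -hook * 0.30  # anti-hook side is -hook * left-normal
        c, s = np.cos(theta), np.sin(theta)
        pts = straight_trace().points_um
        rot = pts @ np.array([[c, s], [-s, c]])  # row-vector R(theta)
        idx = asymmetry_index_frame(FlagellumTrace(rot), straight_cell(hook))
        assert idx == pytest.approx(0.30, abs=1e-6)

    def test_hook_flip_negates_index_exactly(self):
        pts = straight_trace().points_um + np.array([0.0, 10.0])
        tr = FlagellumTrace(pts)
        a = asymmetry_index_frame(tr, straight_cell(1))
        b = asymmetry_index_frame(tr, straight_cell(-1))
        assert a == -b
        assert a != 0

    def test_degenerate_trace_rejected(self):
        tr = FlagellumTrace(np.array([[0.0, 0.0], [1e-12, 0.0]]))
        with pytest.raises(UndefinedIndexError):
            asymmetry_index_frame(tr, straight_cell())


class TestWindowAverage:
    def test_constant_series(self):
        s = np.full(50, 3.25)
        assert window_average(s, 50.0, 25) == 3.25

    def test_enumeration_oracle_center_of_long_movie(self, rng):
        s = rng.normal(size=400)
        got = window_average(s, 200.0, 100, window_s=1.0)
        assert got == pytest.approx(np.mean(s[0:201]), abs=1e-12)

    def test_window_never_crosses_flash(self):
        s = np.concatenate([np.full(200, 1.0), np.full(200, 1e6)])
        got = window_average(s, 200.0, 199, flash_frame=200)
        assert got == 1.0

    def test_whole_movie_window_is_plain_mean(self, rng):
        s = rng.normal(size=30)
        got = window_average(s, 10.0, 15, window_s=100.0)
        assert got == pytest.approx(s.mean(), abs=1e-12)

    def test_edge_uses_one_sided_short_window(self):
        s = np.arange(400, dtype=float)
        lo, hi = window_indices(400, 200.0, 0, window_s=1.0,
                                edge_window_s=0.3)
        assert lo == 0
        assert hi - lo + 1 == 101  # centered window truncated, still >= edge
        lo2, hi2 = window_indices(400, 200.0, 399, window_s=1.0,
                                  edge_window_s=0.3)
        assert hi2 == 399

    def test_nan_frames_skipped_and_all_nan_rejected(self):
        s = np.array([1.0, np.nan, 3.0, np.nan])
        assert window_average(s, 2.0, 1, window_s=4.0) == 2.0
        with pytest.raises(MissingValueError):
            window_average(np.full(10, np.nan), 2.0, 5)


class TestBeatFrequency:
    @pytest.mark.parametrize("f", [3.0, 6.0, 10.0])
    def test_pure_sinusoid_recovered_within_resolution(self, f):
        t = np.arange(200) / 200.0
        s = 0.4 * np.sin(2 * np.pi * f * t + 0.3)
        assert beat_frequency(s, 200.0) == pytest.approx(f, abs=1.0)

    def test_constant_series_reports_zero(self):
        assert beat_frequency(np.full(100, 2.0), 200.0) == 0.0


class TestBeatAmplitude:
    def test_oscillating_midpoint_peak_to_peak(self):
        cell = straight_cell()
        traces = []
        for d in [-15.0, 0.0, 15.0, 0.0]:
            pts = straight_trace().points_um + np.array([0.0, d])
            traces.append(FlagellumTrace(pts))
        assert beat_amplitude(traces, cell) == pytest.approx(30.0, abs=1e-9)

    def test_static_flagellum_is_zero(self):
        traces = [straight_trace(), straight_trace()]
        assert beat_amplitude(traces, straight_cell()) == 0.0

    def test_translation_invariance(self):
        cell = straight_cell()
        traces = [FlagellumTrace(straight_trace().points_um
                                 + np.array([0.0, d])) for d in (-7.0, 7.0)]
        shift = np.array([11.0, -3.0])
        cell2 = CellFrame(cell.head_centroid_um + shift, 0.0, 1,
                          cell.neck_point_um + shift, 0.0)
        traces2 = [FlagellumTrace(t.points_um + shift) for t in traces]
        assert beat_amplitude(traces, cell) == pytest.approx(
            beat_amplitude(traces2, cell2), abs=1e-9)

    def test_needs_two_traces(self):
        with pytest.raises(MissingValueError):
            beat_amplitude([straight_trace()], straight_cell())


class TestFlashResponse:
    def test_equal_phases_give_unity_change(self):
        s = np.full(400, 0.3)
        r = flash_response(s, 200, 100.0)
        assert r.relative_change == pytest.approx(1.0)

    def test_halved_index_gives_half(self):
        s = np.concatenate([np.full(200, 0.4), np.full(200, 0.2)])
        r = flash_response(s, 200, 100.0)
        assert r.pre_index == pytest.approx(0.4)
        assert r.post_index == pytest.approx(0.2)
        assert r.relative_change == pytest.approx(0.5)

    def test_tiny_pre_index_flags_undefined_ratio(self):
        s = np.concatenate([np.full(200, 0.001), np.full(200, 0.2)])
        r = flash_response(s, 200, 100.0)
        assert np.isnan(r.relative_change)


class TestAlignEnvelope:
    def test_single_frame_is_pure_rigid_transform(self, noisefree_movie):
        from spermbeat.io import ImageStack
        from spermbeat.segmentation import analyze_frame
        stack, _ = noisefree_movie
        fa = analyze_frame(stack.frames[0], 1.0)
        one = ImageStack(stack.frames[:1], fps=stack.fps, pixel_size_um=1.0)
        env = align_envelope(one, [fa.cell])
        assert env.n_frames == 1
        assert env.image.shape == stack.frames[0].shape
        # pixel mass approximately preserved by rigid resampling
        assert env.image.sum() == pytest.approx(
            float(stack.frames[0].sum()), rel=0.05)

    def test_no_valid_frames_rejected(self, noisefree_movie):
        stack, _ = noisefree_movie
        with pytest.raises(AlignmentError):
            align_envelope(stack, [None] * stack.n_frames)

    def test_aligned_frames_have_zero_neck_azimuth(self, tethered_movie):
        # post-condition self-check: re-segmenting aligned frames puts the
        # neck at azimuth ~0
        from spermbeat.io import ImageStack
        from spermbeat.segmentation import analyze_frame, analyze_stack
        stack, _ = tethered_movie
        an = analyze_stack(stack)
        cells = [a.cell if a else None for a in an]
        # align a handful of frames individually and re-measure
        ok = 0
        for i in range(0, 50, 10):
            if cells[i] is None:
                continue
            one = ImageStack(stack.frames[i:i + 1], fps=stack.fps,
                             pixel_size_um=1.0)
            env = align_envelope(one, [cells[i]])
            fa = analyze_frame(env.image, 1.0)
            if abs(fa.cell.neck_azimuth_rad) < 0.1:
                ok += 1
        assert ok >= 3
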