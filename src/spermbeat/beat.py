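"""Flagellar-beat quantification: asymmetry index, amplitude, frequency,
flash responses and beat-envelope superposition.

The central quantity is the *asymmetry index*: the signed angle between
the cell's symmetry axis and the line from the head centroid to the middle
of the flagellum (the point at 50% arc length of the traced midline).  The
sign convention follows the hook-shaped head of mouse sperm: deflection
away from the hook side ("anti-hook") is positive, toward it ("pro-hook")
negative, and 0 indicates a symmetric beat.  Per-frame values are averaged
in a 1 s window around each frame; near movie boundaries or a UV flash the
window shrinks to a one-sided ~300 ms window and never crosses the flash.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram
from skimage.transform import AffineTransform, warp

from .errors import (AlignmentError, MissingValueError, ParameterError,
                     UndefinedIndexError)
from .geometry import CellFrame, FlagellumTrace, signed_angle
from .io import ImageStack

__all__ = [
    "BeatMetrics",
    "FlashResponse",
    "EnvelopeImage",
    "asymmetry_index_frame",
    "window_average",
    "window_indices",
    "beat_frequency",
    "beat_amplitude",
    "flash_response",
    "align_envelope",
    "compute_beat_metrics",
]

#: minimum head-to-midpoint distance (µm) below which the index is undefined
_DEGENERATE_UM = 1e-9


@dataclass
class BeatMetrics:
    """Windowed beat parameters attached to one center frame."""

    frame: int
    asymmetry_index_rad: float
    amplitude_um: float
    frequency_hz: float
    window_s: float


@dataclass
class FlashResponse:
    """Asymmetry index 1 s before vs 1 s after a UV flash.

    ``relative_change`` is post/pre, or NaN when the pre-flash index is
    below the floor (the ratio would be meaningless near zero).
    """

    pre_index: float
    post_index: float
    relative_change: float


@dataclass
class EnvelopeImage:
    """Superposition of frames in head-centered, neck-aligned coordinates."""

    image: np.ndarray
    n_frames: int
    n_skipped: int = 0


def asymmetry_index_frame(trace: FlagellumTrace, cell: CellFrame) -> float:
    """Signed asymmetry index (rad) for one frame.

    The index is the angle from the tail-ward cell axis to the line
    head centroid → flagellar midpoint, with the sign flipped so that
    anti-hook deflection is positive regardless of which side the hook
    is on.  Mirroring the cell (which flips ``hook_sign``) negates the
    index exactly.
    """
    if trace.total_arclength_um <= 0:
        raise UndefinedIndexError("trace has zero arc length")
    m = trace.midpoint()
    v = m - cell.head_centroid_um
    if np.linalg.norm(v) < _DEGENERATE_UM:
        raise UndefinedIndexError("flagellar midpoint coincides with head centroid")
    raw = signed_angle(cell.axis_unit(), v)
    return -cell.hook_sign * raw


def window_indices(n_frames: int, fps: float, center_frame: int,
                   window_s: float = 1.0, edge_window_s: float = 0.3,
                   flash_frame: int | None = None) -> tuple[int, int]:
    """Inclusive frame range [lo, hi] of the averaging window at a center.

    The nominal window is ±``window_s``/2 around the center, truncated at
    the movie boundaries and at the flash (a window never mixes pre- and
    post-flash frames).  If truncation leaves fewer frames than an
    ``edge_window_s`` window, a one-sided ``edge_window_s`` window on the
    valid side is used instead.
    """
    if n_frames < 1 or fps <= 0:
        raise ParameterError("need a non-empty series and positive fps")
    if not 0 <= center_frame < n_frames:
        raise ParameterError("center_frame outside the movie")
    vlo, vhi = 0, n_frames - 1
    if flash_frame is not None:
        if center_frame < flash_frame:
            vhi = min(vhi, flash_frame - 1)
        else:
            vlo = max(vlo, flash_frame)
    half = int(round(window_s * fps / 2))
    lo = max(vlo, center_frame - half)
    hi = min(vhi, center_frame + half)
    edge = max(1, int(round(edge_window_s * fps)))
    if hi - lo + 1 < edge:
        # pressed against a boundary: one-sided window on the valid side
        if center_frame - vlo <= vhi - center_frame:
            lo, hi = vlo, min(vhi, vlo + edge - 1)
        else:
            lo, hi = max(vlo, vhi - edge + 1), vhi
    return lo, hi


def window_average(series: np.ndarray, fps: float, center_frame: int,
                   window_s: float = 1.0, edge_window_s: float = 0.3,
                   flash_frame: int | None = None) -> float:
    """Mean of a per-frame series over the window at ``center_frame``.

    NaN entries (dropped frames) are excluded; if no valid frame remains a
    :class:`MissingValueError` is raised.  When the window covers the whole
    movie this reduces to the plain mean of the valid frames.
    """
    series = np.asarray(series, dtype=float)
    lo, hi = window_indices(series.size, fps, center_frame, window_s,
                            edge_window_s, flash_frame)
    vals = series[lo:hi + 1]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise MissingValueError(f"no valid frames in window [{lo}, {hi}]")
    return float(vals.mean())


def beat_frequency(angle_series: np.ndarray, fps: float) -> float:
    """Dominant beat frequency (Hz) of a windowed angle series.

    Hann-tapered periodogram of the mean-subtracted series, excluding the
    zero-frequency bin, with parabolic interpolation of the peak (the 1 s
    windows give coarse spectral bins otherwise).  Returns 0.0 for a
    constant series.
    """
    x = np.asarray(angle_series, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise MissingValueError("need >= 4 valid samples for a spectrum")
    mean = x[finite].mean()
    x = np.where(finite, x, mean) - mean
    if np.allclose(x, 0.0):
        return 0.0
    freqs, power = periodogram(x, fs=fps, window="hann", detrend=False)
    k = int(np.argmax(power[1:])) + 1  # skip DC
    if 1 <= k < power.size - 1:
        pm, p0, pp = power[k - 1], power[k], power[k + 1]
        denom = pm - 2 * p0 + pp
        delta = 0.5 * (pm - pp) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = freqs[1] - freqs[0]
    return float(freqs[k] + delta * df)


def _transverse_distance(point: np.ndarray, cell: CellFrame) -> float:
    """Signed distance of a point to the cell symmetry axis (µm)."""
    u = cell.axis_unit()
    d = point - cell.head_centroid_um
    return float(u[0] * d[1] - u[1] * d[0])


def beat_amplitude(traces: list[FlagellumTrace], cell: CellFrame,
                   mode: str = "midpoint") -> float:
    """Peak-to-peak transverse excursion (µm) across a window of traces.

    ``mode='midpoint'`` (default) measures the flagellar midpoint's signed
    distance to the cell symmetry axis; ``mode='tip'`` uses the distal tip
    instead.
    """
    traces = [t for t in traces if t is not None]
    if len(traces) < 2:
        raise MissingValueError("need >= 2 valid traces for an amplitude")
    if mode == "midpoint":
        pts = [t.midpoint() for t in traces]
    elif mode == "tip":
        pts = [t.points_um[-1] for t in traces]
    else:
        raise ParameterError(f"unknown amplitude mode {mode!r}")
    d = np.array([_transverse_distance(p, cell) for p in pts])
    return float(d.max() - d.min())


def flash_response(index_series: np.ndarray, flash_frame: int, fps: float,
                   window_s: float = 1.0, edge_window_s: float = 0.3,
                   pre_floor: float = 0.01) -> FlashResponse:
    """Pre/post-flash asymmetry comparison.

    ``pre_index`` and ``post_index`` are window averages centered 1 s
    before and after the flash (windows never cross it); the relative
    change normalizes the post value to the pre value, and is NaN when
    |pre| < ``pre_floor`` rad.
    """
    series = np.asarray(index_series, dtype=float)
    n = series.size
    if not 0 < flash_frame < n:
        raise ParameterError("flash_frame must be strictly inside the movie")
    off = int(round(fps))  # 1 s in frames
    c_pre = int(np.clip(flash_frame - off, 0, flash_frame - 1))
    c_post = int(np.clip(flash_frame + off, flash_frame, n - 1))
    pre = window_average(series, fps, c_pre, window_s, edge_window_s, flash_frame)
    post = window_average(series, fps, c_post, window_s, edge_window_s, flash_frame)
    rel = post / pre if abs(pre) >= pre_floor else float("nan")
    return FlashResponse(pre_index=pre, post_index=post, relative_change=rel)


def align_envelope(stack: ImageStack, cells: list[CellFrame | None],
                   reducer: str = "max") -> EnvelopeImage:
    """Superimpose all frames in head-centered, neck-aligned coordinates.

    Each frame is resampled so the head centroid maps to the image center
    and the neck azimuth to angle 0 (the neck points along +x in the
    output), then all frames are reduced pixelwise — maximum projection by
    default, which draws the envelope of all flagellar positions; ``mean``
    is available as an alternative.  Frames whose cell geometry is missing
    (``None`` or no neck) are skipped and counted.
    """
    if reducer not in ("max", "mean"):
        raise ParameterError(f"unknown reducer {reducer!r}")
    h, w = stack.shape
    px = stack.pixel_size_um
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y) px
    acc = None
    n_used = 0
    n_skipped = 0
    for frame, cell in zip(stack.frames, cells):
        if cell is None or cell.neck_azimuth_rad is None:
            n_skipped += 1
            continue
        az = cell.neck_azimuth_rad
        head_px = cell.head_centroid_um / px
        c, s = np.cos(az), np.sin(az)
        rot = np.array([[c, -s], [s, c]])
        shift = head_px - rot @ center
        matrix = np.array([[rot[0, 0], rot[0, 1], shift[0]],
                           [rot[1, 0], rot[1, 1], shift[1]],
                           [0.0, 0.0, 1.0]])
        aligned = warp(frame.astype(float), AffineTransform(matrix=matrix),
                       order=1, mode="constant",
                       cval=float(np.min(frame)), preserve_range=True)
        if acc is None:
            acc = aligned if reducer == "max" else aligned.copy()
        elif reducer == "max":
            acc = np.maximum(acc, aligned)
        else:
            acc += aligned
        n_used += 1
    if acc is None:
        raise AlignmentError("no frame with valid head and neck geometry")
    if reducer == "mean":
        acc /= n_used
    return EnvelopeImage(image=acc, n_frames=n_used, n_skipped=n_skipped)


def compute_beat_metrics(traces: list[FlagellumTrace | None],
                         cells: list[CellFrame | None],
                         fps: float, window_s: float = 1.0,
                         edge_window_s: float = 0.3,
                         flash_frame: int | None = None,
                         amplitude_mode: str = "midpoint") -> pd.DataFrame:
    """Windowed beat metrics for every frame of a movie.

    Builds the per-frame asymmetry-index series (NaN for dropped frames),
    then evaluates the windowed index, amplitude and frequency at each
    center frame.  Returns a table with columns ``frame, time_s,
    asym_index_rad, amplitude_um, frequency_hz, window_s, n_valid``.
    """
    n = len(traces)
    if n != len(cells):
        raise ParameterError("traces and cells must be the same length")
    idx = np.full(n, np.nan)
    for i, (tr, cl) in enumerate(zip(traces, cells)):
        if tr is None or cl is None:
            continue
        try:
            idx[i] = asymmetry_index_frame(tr, cl)
        except UndefinedIndexError:
            pass
    rows = []
    for i in range(n):
        lo, hi = window_indices(n, fps, i, window_s, edge_window_s, flash_frame)
        win = idx[lo:hi + 1]
        n_valid = int(np.isfinite(win).sum())
        try:
            mean_idx = window_average(idx, fps, i, window_s, edge_window_s,
                                      flash_frame)
        except MissingValueError:
            mean_idx = np.nan
        try:
            amp = beat_amplitude([traces[j] for j in range(lo, hi + 1)],
                                 cells[i], mode=amplitude_mode) \
                if cells[i] is not None else np.nan
        except MissingValueError:
            amp = np.nan
        try:
            freq = beat_frequency(win, fps)
        except MissingValueError:
            freq = np.nan
        rows.append({"frame": i, "time_s": i / fps,
                     "asym_index_rad": mean_idx, "amplitude_um": amp,
                     "frequency_hz": freq,
                     "window_s": (hi - lo + 1) / fps, "n_valid": n_valid})
    return pd.DataFrame(rows)
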