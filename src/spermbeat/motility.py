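"""Head tracking, stage compensation and straight-line velocity (VSL).

Free-swimming cells are followed with a normalized-cross-correlation
registration of a head template; recorded motorized-stage offsets are then
added back to recover world coordinates, and VSL — net start-to-end
displacement of the head over elapsed time, the standard progressivity
measure of computer-assisted sperm analysis — is computed on the
stage-compensated track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .errors import MissingValueError, ParameterError, TrackLostError
from .io import ImageStack, StageLog
from .segmentation import clean_mask, iterative_threshold, locate_head

__all__ = ["Track", "track_head", "stage_compensate", "vsl"]


@dataclass
class Track:
    """Stage-compensated world head positions over time."""

    time_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.time_s.size
        if not (self.x_um.size == self.y_um.size == self.valid.size == n):
            raise ParameterError("track arrays must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ParameterError("timestamps must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(self.time_s.size),
                             "time_s": self.time_s, "x_um": self.x_um,
                             "y_um": self.y_um,
                             "valid": self.valid.astype(int)})


def _subpixel_peak(corr: np.ndarray) -> tuple[float, float, float]:
    """Integer argmax of a correlation map refined by 1-D parabolas."""
    r, c = np.unravel_index(np.argmax(corr), corr.shape)
    peak = float(corr[r, c])

    def refine(vals, i, n):
        if 0 < i < n - 1:
            a, b, cc_ = vals[i - 1], vals[i], vals[i + 1]
            denom = a - 2 * b + cc_
            if denom != 0:
                return i + float(np.clip(0.5 * (a - cc_) / denom, -0.5, 0.5))
        return float(i)

    rr = refine(corr[:, c], r, corr.shape[0])
    cc = refine(corr[r, :], c, corr.shape[1])
    return rr, cc, peak


def track_head(stack: ImageStack, expected_area_um2: float = 350.0,
               roi_center_px: tuple[float, float] | None = None,
               template_halfsize_um: float = 6.0,
               search_um: float = 10.0, refresh_every: int = 10,
               corr_floor: float = 0.5, max_lost: int = 5) -> Track:
    """Per-frame head position (image coordinates, µm) by template registration.

    The template is a patch around the head — seeded from segmentation of
    the first frame, or from a user ROI — and is matched by normalized
    cross-correlation within a search window around the previous position,
    with parabolic sub-pixel refinement.  The template is refreshed every
    ``refresh_every`` frames to follow slow appearance changes.  A frame
    whose best correlation falls below ``corr_floor`` is flagged invalid;
    more than ``max_lost`` consecutive invalid frames abort the track.
    """
    px = stack.pixel_size_um
    n = stack.n_frames
    h, w = stack.shape
    if roi_center_px is None:
        try:
            expected = max(1, int(round(expected_area_um2 / px ** 2)))
            seg = iterative_threshold(stack.frames[0], expected)
            cell = locate_head(clean_mask(seg.mask), px,
                               intensity=stack.frames[0])
            roi_center_px = (cell.head_centroid_um[1] / px,
                             cell.head_centroid_um[0] / px)
        except Exception as exc:
            raise TrackLostError(f"could not seed the head ROI: {exc}") from exc

    half = max(2, int(round(template_halfsize_um / px)))
    search = max(1, int(round(search_um / px)))

    def cut(frame, r, c, radius):
        r0, r1 = max(0, int(round(r)) - radius), min(h, int(round(r)) + radius + 1)
        c0, c1 = max(0, int(round(c)) - radius), min(w, int(round(c)) + radius + 1)
        return frame[r0:r1, c0:c1].astype(float), r0, c0

    r_prev, c_prev = roi_center_px
    template, tr0, tc0 = cut(stack.frames[0], r_prev, c_prev, half)
    # head position relative to the template's top-left at cut time
    off_r, off_c = r_prev - tr0, c_prev - tc0
    pos = np.empty((n, 2))
    valid = np.ones(n, dtype=bool)
    pos[0] = (r_prev, c_prev)
    lost_streak = 0
    for i in range(1, n):
        window, wr0, wc0 = cut(stack.frames[i], r_prev, c_prev,
                               half + search)
        if (window.shape[0] < template.shape[0]
                or window.shape[1] < template.shape[1]):
            corr = None
        else:
            corr = match_template(window, template)
        if corr is None or corr.size == 0 or np.nanmax(corr) < corr_floor:
            valid[i] = False
            pos[i] = (r_prev, c_prev)
            lost_streak += 1
            if lost_streak > max_lost:
                raise TrackLostError(
                    f"head lost for {lost_streak} consecutive frames at frame {i}")
            continue
        lost_streak = 0
        rr, cc, _ = _subpixel_peak(corr)
        # peak (rr, cc) is the window position of the template's top-left
        r_new = wr0 + rr + off_r
        c_new = wc0 + cc + off_c
        pos[i] = (r_new, c_new)
        r_prev, c_prev = r_new, c_new
        if refresh_every and i % refresh_every == 0:
            template, tr0, tc0 = cut(stack.frames[i], r_prev, c_prev, half)
            off_r, off_c = r_prev - tr0, c_prev - tc0
    track_img = Track(time_s=stack.times(), x_um=pos[:, 1] * px,
                      y_um=pos[:, 0] * px, valid=valid)
    return track_img


def stage_compensate(track: Track, stage: StageLog | None) -> Track:
    """World track = image-frame track + recorded stage offsets.

    With a zero (or ``None``) stage log this is the identity; with a stage
    that followed the cell, the compensation restores the true swimming
    path.
    """
    if stage is None:
        return track
    if len(stage) != track.time_s.size:
        raise ParameterError(
            f"stage log length {len(stage)} != track length {track.time_s.size}")
    return Track(time_s=track.time_s, x_um=track.x_um + stage.x_um,
                 y_um=track.y_um + stage.y_um, valid=track.valid)


def vsl(track: Track, min_duration_s: float = 1.0) -> float:
    """Straight-line velocity (µm/s) over the full valid track.

    Euclidean distance between the first and last valid positions divided
    by the elapsed time; invariant under rigid motion of the track and
    under time reversal.  Tracks spanning less than ``min_duration_s`` are
    rejected.
    """
    idx = np.flatnonzero(track.valid)
    if idx.size < 2:
        raise MissingValueError("need >= 2 valid track points")
    i0, i1 = idx[0], idx[-1]
    elapsed = track.time_s[i1] - track.time_s[i0]
    if elapsed < min_duration_s:
        raise MissingValueError(
            f"track spans only {elapsed:.3f} s (minimum {min_duration_s} s)")
    dist = float(np.hypot(track.x_um[i1] - track.x_um[i0],
                          track.y_um[i1] - track.y_um[i0]))
    return dist / elapsed
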