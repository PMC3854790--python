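"""Synthetic dark-field sperm movies with analytic ground truth.

The generator renders a mouse sperm cell — elliptical head, a hook-shaped
bulge on one side of the head, and a flagellum — as a bright object on a
dark background, mimicking stroboscopic dark-field movies of cells tethered
to glass by the head.  The flagellar shape is a tangent-angle model

    psi(s, t) = psi0 + kappa_geom * s + A * sin(2*pi*(s/lambda - f*t))

where ``s`` is arc length from the neck, ``A`` the tangent-angle wave
amplitude (rad), ``lambda`` the wavelength, ``f`` the beat frequency, and
``kappa_geom`` the static (intrinsic) curvature.  The signed parameter
``static_curvature_per_um`` (kappa0) is defined so that *positive* values
bend the flagellum away from the hook side ("anti-hook"), negative values
toward it ("pro-hook"); internally ``kappa_geom = -hook_sign * kappa0``.
The midline is obtained by integrating (cos psi, sin psi) along arc length
from the tether anchor.

Every simulated movie carries a :class:`GroundTruth` with the analytic
noise-free midlines, the per-frame asymmetry index computed on them, and
the planted beat frequency / path speed, so recovery by the image pipeline
can be scored exactly.

Default waveform values are chosen to resemble the beating of mouse sperm
in shallow observation chambers: a 120 µm flagellum beating at 6 Hz with a
midpoint peak-to-peak excursion of ~31 µm (the tangent-angle amplitude
0.44 rad is calibrated to that excursion), and static curvatures up to
±0.01 µm⁻¹ giving asymmetry indices up to ≈0.3 rad.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi
from scipy.integrate import cumulative_trapezoid
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation
from skimage.morphology import disk as disk_footprint

from .beat import asymmetry_index_frame
from .errors import GeometryError, ParameterError
from .geometry import CellFrame, FlagellumTrace, unit
from .io import ImageStack, StageLog
from .photometry import FluorescenceTrace

__all__ = [
    "WaveformParams",
    "RenderParams",
    "GroundTruth",
    "build_midline",
    "analytic_cell_frame",
    "simulate_tethered_movie",
    "simulate_freeswim_movie",
    "simulate_flash_experiment",
]

#: arc-length integration step (µm) for analytic midlines
DEFAULT_DS_UM = 0.1


@dataclass(frozen=True)
class WaveformParams:
    """Ground-truth flagellar waveform and cell geometry.

    Attributes
    ----------
    flagellum_length_um
        Flagellum length L (µm), neck to tip.
    static_curvature_per_um
        kappa0 (µm⁻¹); positive bends anti-hook, negative pro-hook.
    wave_amplitude
        Tangent-angle amplitude A (rad) of the traveling wave.
    beat_frequency_hz
        Beat frequency f (Hz).
    wavelength_um
        Wavelength lambda (µm) of the traveling curvature wave.
    hook_sign
        +1 / −1: side of the head hook relative to the oriented cell axis.
    head_length_um, head_width_um
        Axes of the elliptical head.
    anchor_xy_um
        Tether point (x, y) in µm — the neck, where the flagellum starts.
    base_angle_rad
        Direction of the cell symmetry axis (tail-ward); the flagellum
        extends from the anchor in this direction.
    """

    flagellum_length_um: float = 120.0
    static_curvature_per_um: float = 0.0
    wave_amplitude: float = 0.44
    beat_frequency_hz: float = 6.0
    wavelength_um: float = 120.0
    hook_sign: int = 1
    head_length_um: float = 8.0
    head_width_um: float = 4.0
    anchor_xy_um: tuple[float, float] = (28.0, 96.0)
    base_angle_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.flagellum_length_um <= 0:
            raise ParameterError("flagellum_length_um must be > 0")
        if self.wavelength_um <= 0:
            raise ParameterError("wavelength_um must be > 0")
        if self.beat_frequency_hz < 0:
            raise ParameterError("beat_frequency_hz must be >= 0")
        if abs(self.hook_sign) != 1:
            raise ParameterError("hook_sign must be +1 or -1")
        if self.wave_amplitude < 0:
            raise ParameterError("wave_amplitude must be >= 0")
        if self.head_length_um <= 0 or self.head_width_um <= 0:
            raise ParameterError("head dimensions must be > 0")


@dataclass(frozen=True)
class RenderParams:
    """Rendering / acquisition parameters for synthetic movies.

    ``foreground_level`` must exceed ``background_level`` (bright cell on
    dark background, dark-field convention).  ``exposure_s`` is metadata
    only (the stroboscopic pulse length); motion blur is not rendered.
    """

    fps: float = 200.0
    pixel_size_um: float = 1.0
    image_shape: tuple[int, int] = (192, 176)
    psf_sigma_um: float = 0.6
    noise_sd: float = 20.0
    background_level: float = 100.0
    foreground_level: float = 1000.0
    flagellum_brightness: float = 0.6
    exposure_s: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if self.foreground_level <= self.background_level:
            raise ParameterError("foreground_level must exceed background_level")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Analytic ground truth attached to a simulated movie."""

    midlines: list[FlagellumTrace]
    frame_asymmetry_index: np.ndarray
    true_asymmetry_index: float
    true_frequency_hz: float
    true_vsl_um_s: float | None = None
    flash_frame: int | None = None
    pre_index: float | None = None
    post_index: float | None = None
    head_world_um: np.ndarray | None = None

    def summary(self) -> dict:
        """JSON-serializable scalar summary (omits the full midlines)."""
        return {
            "true_asymmetry_index": self.true_asymmetry_index,
            "true_frequency_hz": self.true_frequency_hz,
            "true_vsl_um_s": self.true_vsl_um_s,
            "flash_frame": self.flash_frame,
            "pre_index": self.pre_index,
            "post_index": self.post_index,
            "frame_asymmetry_index": self.frame_asymmetry_index,
        }


def build_midline(params: WaveformParams, t: float,
                  ds_um: float = DEFAULT_DS_UM) -> FlagellumTrace:
    """Analytic flagellar midline at time ``t`` (s).

    Integrates the tangent-angle model with the trapezoid rule on an arc-
    length grid of step ``ds_um``; the returned polyline starts at the
    anchor (neck) and has total arc length L to within discretization
    error (< 0.1 µm at the default step for L = 120 µm).
    """
    if t < 0:
        raise ParameterError("t must be >= 0")
    L = params.flagellum_length_um
    n = max(2, int(np.ceil(L / ds_um)) + 1)
    s = np.linspace(0.0, L, n)
    kappa_geom = -params.hook_sign * params.static_curvature_per_um
    psi = (params.base_angle_rad + kappa_geom * s
           + params.wave_amplitude
           * np.sin(2 * np.pi * (s / params.wavelength_um
                                 - params.beat_frequency_hz * t)))
    x0, y0 = params.anchor_xy_um
    x = x0 + cumulative_trapezoid(np.cos(psi), s, initial=0.0)
    y = y0 + cumulative_trapezoid(np.sin(psi), s, initial=0.0)
    return FlagellumTrace(np.column_stack([x, y]), arclength_um=s)


def analytic_cell_frame(params: WaveformParams) -> CellFrame:
    """Ground-truth :class:`CellFrame` matching the rendered cell.

    The head centroid sits half a head length behind the anchor along the
    cell axis; the neck is the anchor itself.
    """
    u = unit(params.base_angle_rad)
    anchor = np.asarray(params.anchor_xy_um, dtype=float)
    centroid = anchor - 0.5 * params.head_length_um * u
    return CellFrame(
        head_centroid_um=centroid,
        head_axis_angle_rad=params.base_angle_rad,
        hook_sign=params.hook_sign,
        neck_point_um=anchor,
        neck_azimuth_rad=params.base_angle_rad,
    )


# -- rasterization -----------------------------------------------------------

#: supersampling factor for rasterization; the silhouette is drawn on a
#: finer grid and block-averaged down, emulating pixel integration, so the
#: few-pixel head carries its true subpixel shape and orientation
_SUPERSAMPLE = 4


def _cell_silhouette(midline: FlagellumTrace, params: WaveformParams,
                     render: RenderParams,
                     flagellum_thickness_um: float = 1.0) -> np.ndarray:
    """Cell silhouette on the pixel grid, 1.0 at the head/hook and
    ``flagellum_brightness`` along the flagellum (in dark-field movies the
    compact head scatters far more light than the thin flagellum)."""
    h, w = render.image_shape
    px = render.pixel_size_um
    u = unit(params.base_angle_rad)
    nvec = np.array([-u[1], u[0]])  # left normal of the axis
    anchor = np.asarray(params.anchor_xy_um, dtype=float)
    centroid = anchor - 0.5 * params.head_length_um * u
    # lateral bulge at the centroid level marking the hook side of the
    # falciform head; placed mid-head so both head ends stay symmetric
    hook_radius = 0.4 * params.head_length_um / 2
    hook_center = (centroid + params.hook_sign
                   * (0.5 * params.head_width_um + 0.5 * hook_radius) * nvec)

    pts = midline.points_um
    extent = np.vstack([pts, centroid[None, :], hook_center[None, :]])
    margin = max(params.head_width_um, flagellum_thickness_um)
    if (extent[:, 0].min() < margin or extent[:, 1].min() < margin
            or extent[:, 0].max() > (w - 1) * px - margin
            or extent[:, 1].max() > (h - 1) * px - margin):
        raise GeometryError("cell does not fit inside the image; enlarge "
                            "image_shape or move the anchor")

    ss = _SUPERSAMPLE
    hs, ws = h * ss, w * ss
    ss_px = px / ss

    def to_ss(um: float) -> float:
        # native pixel r covers supersample rows r*ss .. r*ss+ss-1, so a
        # µm coordinate maps to supersample index (um/px + 0.5)*ss - 0.5
        return (um / px + 0.5) * ss - 0.5

    # flagellum: stamp the polyline on the fine grid, thicken by dilation
    rr = np.clip(np.round(to_ss(pts[:, 1])).astype(int), 0, hs - 1)
    cc = np.clip(np.round(to_ss(pts[:, 0])).astype(int), 0, ws - 1)
    flag = np.zeros((hs, ws), dtype=bool)
    flag[rr, cc] = True
    radius_ss = int(round(0.5 * flagellum_thickness_um / ss_px))
    if radius_ss >= 1:
        flag = dilation(flag, disk_footprint(radius_ss))
    # head ellipse (skimage rotation is about the row axis; with (row, col)
    # = (y, x) passing -base_angle orients the major axis along the cell axis)
    head = np.zeros((hs, ws), dtype=bool)
    err, ecc = draw_ellipse(to_ss(centroid[1]), to_ss(centroid[0]),
                            0.5 * params.head_width_um / ss_px,
                            0.5 * params.head_length_um / ss_px,
                            shape=(hs, ws), rotation=-params.base_angle_rad)
    head[err, ecc] = True
    hrr, hcc = draw_disk((to_ss(hook_center[1]), to_ss(hook_center[0])),
                         hook_radius / ss_px, shape=(hs, ws))
    head[hrr, hcc] = True
    fine = np.maximum(head.astype(np.float32),
                      render.flagellum_brightness * flag.astype(np.float32))
    # pixel integration: block-average back to the sensor grid
    return fine.reshape(h, ss, w, ss).mean(axis=(1, 3))


def _render_frame(silhouette: np.ndarray, render: RenderParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Blur + scale + noise + quantize a silhouette into a uint16 frame."""
    sigma_px = render.psf_sigma_um / render.pixel_size_um
    img = ndi.gaussian_filter(silhouette, sigma_px)
    img = render.background_level + (render.foreground_level
                                     - render.background_level) * img
    if render.noise_sd > 0:
        img = img + rng.normal(0.0, render.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def _frame_count(duration_s: float, fps: float) -> int:
    n = int(round(duration_s * fps))
    if n < 2:
        raise ParameterError("movie must contain at least 2 frames")
    return n


def simulate_tethered_movie(wave: WaveformParams, render: RenderParams,
                            duration_s: float) -> tuple[ImageStack, GroundTruth]:
    """Movie of a head-tethered cell with a freely beating flagellum.

    The head stays at the anchor in every frame.  Ground truth carries the
    analytic midlines and the asymmetry index evaluated on them.
    """
    n = _frame_count(duration_s, render.fps)
    rng = np.random.default_rng(render.seed)
    cell = analytic_cell_frame(wave)
    frames = np.empty((n, *render.image_shape), dtype=np.uint16)
    midlines: list[FlagellumTrace] = []
    idx = np.empty(n)
    for i in range(n):
        ml = build_midline(wave, i / render.fps)
        midlines.append(ml)
        idx[i] = asymmetry_index_frame(ml, cell)
        frames[i] = _render_frame(_cell_silhouette(ml, wave, render), render, rng)
    stack = ImageStack(frames, fps=render.fps, pixel_size_um=render.pixel_size_um)
    gt = GroundTruth(midlines=midlines, frame_asymmetry_index=idx,
                     true_asymmetry_index=float(idx.mean()),
                     true_frequency_hz=wave.beat_frequency_hz)
    return stack, gt


def simulate_freeswim_movie(path_speed_um_s: float, wiggle: WaveformParams,
                            render: RenderParams, duration_s: float,
                            stage_follows: bool = True,
                            lateral_amplitude_um: float = 2.0,
                            ) -> tuple[ImageStack, StageLog, GroundTruth]:
    """Movie of a progressively swimming cell, optionally stage-tracked.

    The head moves along a straight world path at ``path_speed_um_s``
    (opposite to the flagellum direction) plus a zero-mean lateral yaw
    oscillation at the beat frequency.  With ``stage_follows`` the stage
    cancels the net drift — as when an experimenter keeps the cell centered
    with a motorized stage — and the per-frame stage offsets are logged, so
    that world position = image position + stage offset.  Ground truth VSL
    equals the prescribed path speed.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    n = _frame_count(duration_s, render.fps)
    rng = np.random.default_rng(render.seed)
    swim_dir = -unit(wiggle.base_angle_rad)
    nvec = np.array([-swim_dir[1], swim_dir[0]])
    anchor0 = np.asarray(wiggle.anchor_xy_um, dtype=float)
    f = wiggle.beat_frequency_hz

    frames = np.empty((n, *render.image_shape), dtype=np.uint16)
    midlines: list[FlagellumTrace] = []
    head_world = np.empty((n, 2))
    stage = np.zeros((n, 2))
    for i in range(n):
        t = i / render.fps
        drift = path_speed_um_s * t * swim_dir
        lateral = lateral_amplitude_um * np.sin(2 * np.pi * f * t) * nvec
        world_anchor = anchor0 + drift + lateral
        if stage_follows:
            stage[i] = drift
        image_anchor = world_anchor - stage[i]
        w_i = replace(wiggle, anchor_xy_um=tuple(image_anchor))
        ml = build_midline(w_i, t)
        midlines.append(ml)
        frames[i] = _render_frame(_cell_silhouette(ml, w_i, render), render, rng)
        # report the head centroid (what the tracker follows), not the neck
        head_world[i] = (world_anchor
                         - 0.5 * wiggle.head_length_um * unit(wiggle.base_angle_rad))
    stack = ImageStack(frames, fps=render.fps, pixel_size_um=render.pixel_size_um)
    log = StageLog(stage[:, 0].copy(), stage[:, 1].copy())
    gt = GroundTruth(midlines=midlines,
                     frame_asymmetry_index=np.zeros(n),
                     true_asymmetry_index=0.0,
                     true_frequency_hz=f,
                     true_vsl_um_s=float(path_speed_um_s),
                     head_world_um=head_world)
    return stack, log, gt


def simulate_flash_experiment(wave_pre: WaveformParams,
                              wave_post: WaveformParams,
                              render: RenderParams, flash_frame: int,
                              duration_s: float = 4.0,
                              f_baseline: float = 1000.0,
                              f_post: float = 600.0,
                              f_background: float = 50.0,
                              trace_noise_sd: float = 5.0,
                              ) -> tuple[ImageStack, GroundTruth, FluorescenceTrace]:
    """UV-flash experiment: waveform and Ca²⁺ indicator both change at the flash.

    Frames before ``flash_frame`` use ``wave_pre``, frames from it onward
    ``wave_post`` (a caged Ca²⁺ chelator released by the flash lowers
    intracellular Ca²⁺ and with it the static curvature).  The emitted
    fluorescence trace steps down from ``f_baseline`` to ``f_post`` at the
    flash, on a constant background, with Gaussian noise.
    """
    n = _frame_count(duration_s, render.fps)
    if not 0 < flash_frame < n - 1:
        raise ParameterError(
            f"flash_frame must be strictly inside the movie (1..{n - 2})")
    rng = np.random.default_rng(render.seed)
    frames = np.empty((n, *render.image_shape), dtype=np.uint16)
    midlines: list[FlagellumTrace] = []
    idx = np.empty(n)
    for i in range(n):
        wave = wave_pre if i < flash_frame else wave_post
        cell = analytic_cell_frame(wave)
        ml = build_midline(wave, i / render.fps)
        midlines.append(ml)
        idx[i] = asymmetry_index_frame(ml, cell)
        frames[i] = _render_frame(_cell_silhouette(ml, wave, render), render, rng)
    stack = ImageStack(frames, fps=render.fps,
                       pixel_size_um=render.pixel_size_um,
                       flash_frame=flash_frame)
    level = np.where(np.arange(n) < flash_frame, f_baseline, f_post)
    raw = level + f_background + rng.normal(0.0, trace_noise_sd, size=n)
    trace = FluorescenceTrace(time_s=np.arange(n) / render.fps, raw=raw,
                              background=f_background, event_frame=flash_frame)
    gt = GroundTruth(midlines=midlines, frame_asymmetry_index=idx,
                     true_asymmetry_index=float(idx.mean()),
                     true_frequency_hz=wave_pre.beat_frequency_hz,
                     flash_frame=flash_frame,
                     pre_index=float(idx[:flash_frame].mean()),
                     post_index=float(idx[flash_frame:].mean()))
    return stack, gt, trace
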