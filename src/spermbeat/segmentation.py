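"""Cell segmentation and midline extraction from dark-field frames.

The binarization follows the target-area rule: starting from the brightest
intensity present, the threshold is lowered until the foreground reaches an
expected cell area, which makes the segmentation robust to illumination
changes.  The mask is skeletonized and the longest skeleton path starting
near the head is taken as the flagellar midline; the head pose comes from
the moments of the wide (head) part of the mask, and the neck is located
with an annular mask around the head centroid (16 µm inner / 20 µm outer
diameter by default, sized to cover the head and catch the first pixels of
the neck).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.measure import label
from skimage.morphology import skeletonize

from .errors import (GeometryError, HeadError, NeckError, SegmentationError,
                     TraceError)
from .geometry import CellFrame, FlagellumTrace, unit, wrap_angle
from .io import ImageStack

__all__ = [
    "SegmentationResult",
    "FrameAnalysis",
    "iterative_threshold",
    "clean_mask",
    "extract_midline",
    "locate_head",
    "locate_neck",
    "analyze_frame",
    "analyze_stack",
    "frame_table",
]


@dataclass
class SegmentationResult:
    """Binary mask plus the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float
    area_px: int


@dataclass
class FrameAnalysis:
    """Everything extracted from one frame of a movie."""

    frame: int
    segmentation: SegmentationResult
    cell: CellFrame
    trace: FlagellumTrace


def iterative_threshold(frame: np.ndarray, expected_area_px: int) -> SegmentationResult:
    """Binarize by lowering the threshold until the expected area is reached.

    Scans the frame's unique intensity values in descending order and
    returns the highest threshold whose foreground (pixels >= threshold)
    covers at least ``expected_area_px``.  The frame minimum is not a valid
    threshold (it would select the entire image), so a flat or blank frame
    fails.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise SegmentationError("empty frame", last_area=0)
    if expected_area_px < 1:
        raise SegmentationError("expected_area_px must be >= 1")
    values = np.unique(frame)           # ascending
    candidates = values[1:]             # exclude the minimum (whole image)
    if candidates.size == 0:
        raise SegmentationError("flat frame: no contrast to threshold",
                                last_area=int(frame.size))
    flat = np.sort(frame, axis=None)
    # area at threshold t = number of pixels >= t
    areas = frame.size - np.searchsorted(flat, candidates, side="left")
    ok = areas >= expected_area_px
    if not ok.any():
        raise SegmentationError(
            f"no threshold reaches {expected_area_px} px",
            last_area=int(areas[0]))
    # highest threshold with sufficient area = last True (areas decrease
    # with increasing threshold, so True entries form a prefix)
    i = int(np.flatnonzero(ok)[-1])
    t = candidates[i]
    return SegmentationResult(mask=frame >= t, threshold_used=float(t),
                              area_px=int(areas[i]))


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the largest connected component and fill holes."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask", last_area=0)
    labels = label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = labels == int(np.argmax(counts))
    return ndi.binary_fill_holes(keep)


# -- skeleton graph helpers --------------------------------------------------

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray) -> dict[tuple[int, int], list[tuple[tuple[int, int], float]]]:
    """8-connected adjacency of skeleton pixels with Euclidean step weights."""
    pixels = set(zip(*np.nonzero(skel)))
    graph: dict = {p: [] for p in pixels}
    for r, c in pixels:
        for dr, dc in _OFFSETS:
            q = (r + dr, c + dc)
            if q in graph:
                graph[(r, c)].append((q, np.hypot(dr, dc)))
    return graph


def _dijkstra(graph, start):
    dist = {start: 0.0}
    parent = {start: None}
    heap = [(0.0, start)]
    while heap:
        d, node = heapq.heappop(heap)
        if d > dist.get(node, np.inf):
            continue
        for nb, w in graph[node]:
            nd = d + w
            if nd < dist.get(nb, np.inf):
                dist[nb] = nd
                parent[nb] = node
                heapq.heappush(heap, (nd, nb))
    return dist, parent


def _prune_short_spurs(graph, min_len_px: float):
    """Iteratively remove leaf branches shorter than ``min_len_px``.

    Only branches terminating at a junction (degree >= 3) are removed, so
    the two ends of the main midline path are never pruned away.
    """
    changed = True
    while changed:
        changed = False
        endpoints = [p for p, nbs in graph.items() if len(nbs) == 1]
        for ep in endpoints:
            branch = [ep]
            node, length = ep, 0.0
            prev = None
            while True:
                nbs = [(q, w) for q, w in graph[node] if q != prev]
                if len(graph[node]) >= 3 or not nbs:
                    break
                q, w = nbs[0]
                length += w
                if len(graph[q]) >= 3:
                    if length < min_len_px:
                        for b in branch:
                            for nb, _ in graph.pop(b):
                                graph[nb] = [(n, w2) for n, w2 in graph[nb]
                                             if n != b]
                        changed = True
                    break
                branch.append(q)
                prev, node = node, q
                if length >= min_len_px:
                    break
    return graph


def extract_midline(mask: np.ndarray, head_centroid_um: np.ndarray,
                    pixel_size_um: float, min_length_um: float = 20.0,
                    prune_um: float = 5.0, trim_radius_um: float = 8.0,
                    smooth_window: int = 5) -> FlagellumTrace:
    """Skeletonize the mask and order the flagellar midline head → tip.

    The skeleton is turned into a graph, spurs shorter than ``prune_um``
    are removed, and the longest geodesic path starting from the skeleton node
    nearest the head centroid is taken as the midline.  Points within
    ``trim_radius_um`` of the head centroid (inside the head) are dropped
    so the trace starts at the neck, and the trace is lightly smoothed
    with a moving average.
    """
    skel = skeletonize(np.asarray(mask, dtype=bool))
    graph = _skeleton_graph(skel)
    if not graph:
        raise TraceError("skeleton is empty")
    graph = _prune_short_spurs(graph, prune_um / pixel_size_um)
    if not graph:
        raise TraceError("skeleton vanished during pruning")
    head_px = np.array([head_centroid_um[1], head_centroid_um[0]]) / pixel_size_um
    # geodesic from the skeleton node nearest the head to the farthest
    # node: the longest path away from the head is the flagellum
    start = min(graph, key=lambda p: (p[0] - head_px[0]) ** 2
                + (p[1] - head_px[1]) ** 2)
    dist, parent = _dijkstra(graph, start)
    end = max(dist, key=dist.get)
    path = []
    node = end
    while node is not None:
        path.append(node)
        node = parent[node]
    path.reverse()
    pts = np.array([(c * pixel_size_um, r * pixel_size_um) for r, c in path])
    # drop the intra-head part so the trace starts at the neck
    d_head = np.linalg.norm(pts - np.asarray(head_centroid_um), axis=1)
    outside = np.flatnonzero(d_head >= trim_radius_um)
    if outside.size >= 2:
        pts = pts[outside[0]:]
    if len(pts) < 2:
        raise TraceError("midline too short after trimming")
    if smooth_window > 1 and len(pts) > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        # odd reflection preserves straight segments (and so endpoints)
        padded = np.pad(pts, ((pad, pad), (0, 0)), mode="reflect",
                        reflect_type="odd")
        pts = np.column_stack([np.convolve(padded[:, 0], kernel, mode="valid"),
                               np.convolve(padded[:, 1], kernel, mode="valid")])
    # collapse any zero-length steps introduced by rounding/smoothing
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    pts = pts[keep]
    if len(pts) < 2:
        raise TraceError("degenerate midline")
    trace = FlagellumTrace(pts)
    if trace.total_arclength_um < min_length_um:
        raise TraceError(f"midline only {trace.total_arclength_um:.1f} µm "
                         f"(minimum {min_length_um} µm)")
    return trace


def locate_head(mask: np.ndarray, pixel_size_um: float,
                intensity: np.ndarray | None = None,
                core_radius_um: float = 1.5,
                head_halfwidth_um: float = 1.2,
                head_halflength_um: float = 3.5,
                near_um: np.ndarray | None = None) -> CellFrame:
    """Head centroid, symmetry-axis angle and hook side.

    The head blob is found either by brightness — in dark-field movies the
    compact head scatters far more light than the thin flagellum, so with
    ``intensity`` given the head is the brightest connected region of the
    mask — or, on a bare mask, as the widest part of the silhouette
    (pixels whose distance to the mask boundary exceeds ``core_radius_um``,
    around the global maximum).  The centroid is the blob centroid; the
    symmetry-axis angle is the blob's principal axis, refined by a few
    trimming iterations that exclude pixels further than
    ``head_halfwidth_um`` from the axis so the one-sided hook does not
    tilt it; the hook side is the sign of the untrimmed third central
    moment transverse to that axis.  The axis orientation is only defined
    modulo π until the neck resolves it (see :func:`analyze_frame`); neck
    fields are left unset.
    """
    mask = np.asarray(mask, dtype=bool)
    if intensity is not None:
        vals = np.asarray(intensity, dtype=float)
        inside = vals[mask]
        if inside.size == 0:
            raise HeadError("empty mask")
        lo, hi = float(inside.min()), float(inside.max())
        if hi <= lo:
            raise HeadError("no brightness contrast inside the mask")
        if near_um is not None:
            # reference the cut to the local brightness around a known
            # head location (e.g. from the temporal median of a tethered
            # movie): where the beating flagellum self-approaches, blurred
            # strands can outshine the head and a global cut misses it
            hint_rc = np.array([near_um[1], near_um[0]]) / pixel_size_um
            h, w = mask.shape
            yy, xx = np.mgrid[0:h, 0:w]
            nearby = mask & (np.hypot(yy - hint_rc[0], xx - hint_rc[1])
                             <= 5.0 / pixel_size_um)
            if not nearby.any():
                raise HeadError("no foreground near the head hint")
            hi = float(vals[nearby].max())
        cut = lo + 0.5 * (hi - lo)
        core = mask & (vals >= cut)
        if not core.any():
            raise HeadError("no bright head region found")
        labels = label(core, connectivity=2)
        if near_um is not None:
            best, best_d = 0, np.inf
            for lab_id in range(1, labels.max() + 1):
                rr, cc = np.nonzero(labels == lab_id)
                d = np.hypot(rr.mean() - hint_rc[0], cc.mean() - hint_rc[1])
                if d < best_d:
                    best, best_d = lab_id, d
            if best_d * pixel_size_um > 8.0:
                raise HeadError("no bright blob near the head hint")
            rr, cc = np.nonzero(labels == best)
        else:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            rr, cc = np.nonzero(labels == int(np.argmax(counts)))
        wts = vals[rr, cc] - cut
    else:
        edt = ndi.distance_transform_edt(mask) * pixel_size_um
        if edt.max() <= core_radius_um:
            raise HeadError("no region wider than the flagellum found")
        core = edt > core_radius_um
        labels = label(core, connectivity=2)
        peak = np.unravel_index(np.argmax(edt), edt.shape)
        rr, cc = np.nonzero(labels == labels[peak])
        wts = np.ones(rr.size)
    x = cc * pixel_size_um
    y = rr * pixel_size_um

    # the axis is fitted on a narrow ribbon along the current axis
    # estimate, iteratively recentered, so neither the one-sided hook nor
    # the brightness halo can tilt it; unweighted moments inside the
    # ribbon are less hook-biased than intensity-weighted ones
    wsum = float(wts.sum())
    cx = float((wts * x).sum() / wsum)
    cy = float((wts * y).sum() / wsum)
    dx0, dy0 = x - cx, y - cy
    angle = 0.5 * np.arctan2(2 * (wts * dx0 * dy0).sum(),
                             (wts * dx0 * dx0).sum() - (wts * dy0 * dy0).sum())
    if intensity is not None:
        # Refine pose on the continuous intensity in a neighborhood of
        # the head, fitting only the two end slabs of the head (|along|
        # between ``amin`` and ``amax``).  Both transverse sides are
        # included, so every along-axis column of the symmetric head has
        # its transverse centroid on the axis; the mid-head region — the
        # only place the one-sided hook lives — is excluded, and the two
        # symmetric end cuts cancel each other's truncation effects.
        # The widely separated end caps give the orientation a long
        # lever arm.
        vals_img = np.asarray(intensity, dtype=float)
        h_img, w_img = vals_img.shape
        yy, xx = np.mgrid[0:h_img, 0:w_img]
        xa = xx.ravel() * pixel_size_um
        ya = yy.ravel() * pixel_size_um
        amin = head_halflength_um - 1.3
        amax = head_halflength_um + 1.5
        nearby = np.hypot(xa - cx, ya - cy) <= amax + 2 * head_halfwidth_um
        xa, ya = xa[nearby], ya[nearby]
        wa = np.clip(vals_img.ravel()[nearby] - lo, 0.0, None)
        for _ in range(5):
            u = unit(angle)
            along = u[0] * (xa - cx) + u[1] * (ya - cy)
            trans = u[0] * (ya - cy) - u[1] * (xa - cx)
            sel = ((np.abs(along) >= amin) & (np.abs(along) <= amax)
                   & (np.abs(trans) <= 3.0 * head_halfwidth_um))
            w = wa[sel]
            if w.sum() <= 0 or sel.sum() < 4:
                break
            bx = float((w * xa[sel]).sum() / w.sum())
            by = float((w * ya[sel]).sum() / w.sum())
            dx, dy = xa[sel] - bx, ya[sel] - by
            angle = 0.5 * np.arctan2(2 * (w * dx * dy).sum(),
                                     (w * dx * dx).sum() - (w * dy * dy).sum())
            # lateral recenter onto the fitted axis; keep the along position
            u2 = unit(angle)
            lat = (bx - cx) * (-u2[1]) + (by - cy) * u2[0]
            cx, cy = cx - lat * u2[1], cy + lat * u2[0]
    u = unit(angle)
    transverse = u[0] * (y - cy) - u[1] * (x - cx)
    skew = float((wts * transverse ** 3).sum())  # full blob incl. hook
    hook = 1 if skew >= 0 else -1
    return CellFrame(head_centroid_um=np.array([cx, cy]),
                     head_axis_angle_rad=angle, hook_sign=hook)


def locate_neck(mask: np.ndarray, head_centroid_um: np.ndarray,
                pixel_size_um: float, inner_d_um: float = 16.0,
                outer_d_um: float = 20.0) -> tuple[np.ndarray, float]:
    """Neck point and azimuth from an annular mask around the head.

    The annulus (default 16 µm inner / 20 µm outer diameter) covers the
    head, so the only foreground inside the band is the proximal flagellum;
    its centroid is the neck point and its direction from the head centroid
    the neck azimuth.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    cx, cy = np.asarray(head_centroid_um, dtype=float)
    r_out = outer_d_um / 2
    if (cx - r_out < 0 or cy - r_out < 0
            or cx + r_out > (w - 1) * pixel_size_um
            or cy + r_out > (h - 1) * pixel_size_um):
        raise GeometryError("neck annulus does not fit inside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx * pixel_size_um - cx, yy * pixel_size_um - cy)
    band = mask & (dist >= inner_d_um / 2) & (dist <= r_out)
    if not band.any():
        raise NeckError("no foreground pixels inside the neck annulus")
    rr, cc = np.nonzero(band)
    nx = float(cc.mean()) * pixel_size_um
    ny = float(rr.mean()) * pixel_size_um
    azimuth = float(np.arctan2(ny - cy, nx - cx))
    return np.array([nx, ny]), azimuth


def analyze_frame(frame: np.ndarray, pixel_size_um: float,
                  expected_area_um2: float = 350.0,
                  inner_d_um: float = 16.0, outer_d_um: float = 20.0,
                  min_length_um: float = 20.0,
                  denoise_sigma_px: float = 1.0,
                  head_hint_um: np.ndarray | None = None) -> FrameAnalysis:
    """Full single-frame pipeline: threshold → clean → head → neck → midline.

    The frame is lightly Gaussian-smoothed (``denoise_sigma_px``) before
    thresholding so shot noise does not fragment the thin flagellum; the
    reported threshold refers to the smoothed image.  The head-axis
    orientation is flipped, if needed, to point through the neck
    (tail-ward); flipping the axis also flips the transverse direction and
    therefore the hook sign.
    """
    work = np.asarray(frame, dtype=float)
    if denoise_sigma_px > 0:
        work = ndi.gaussian_filter(work, denoise_sigma_px)
    expected_px = max(1, int(round(expected_area_um2 / pixel_size_um ** 2)))
    seg = iterative_threshold(work, expected_px)
    mask = clean_mask(seg.mask)
    cell = locate_head(mask, pixel_size_um, intensity=work, near_um=head_hint_um)
    neck_point, azimuth = locate_neck(mask, cell.head_centroid_um,
                                      pixel_size_um, inner_d_um, outer_d_um)
    axis = cell.head_axis_angle_rad
    hook = cell.hook_sign
    if np.cos(axis - azimuth) < 0:  # orient the axis toward the neck
        axis = wrap_angle(axis + np.pi)
        hook = -hook
    cell = CellFrame(head_centroid_um=cell.head_centroid_um,
                     head_axis_angle_rad=axis, hook_sign=hook,
                     neck_point_um=neck_point, neck_azimuth_rad=azimuth)
    trace = extract_midline(mask, cell.head_centroid_um, pixel_size_um,
                            min_length_um=min_length_um,
                            trim_radius_um=inner_d_um / 2)
    return FrameAnalysis(frame=-1, segmentation=seg, cell=cell, trace=trace)


def analyze_stack(stack: ImageStack, expected_area_um2: float = 350.0,
                  inner_d_um: float = 16.0, outer_d_um: float = 20.0,
                  min_length_um: float = 20.0,
                  consolidate_cell: bool = True) -> list[FrameAnalysis | None]:
    """Run :func:`analyze_frame` on every frame; failed frames become ``None``.

    A temporal median image seeds the head location: in head-tethered
    movies the head is the only persistent bright structure, so its median
    survives while the beating flagellum averages out.  Frames that fail
    segmentation or tracing are dropped (not interpolated); downstream
    windowed statistics simply skip them.

    With ``consolidate_cell`` (default, for head-tethered movies) the head
    centroid, symmetry-axis angle and hook sign — which are physically
    constant while the cell is tethered by the head — are fitted once on
    the temporal median image, where the beating flagellum has averaged
    away and the noise is suppressed, and shared by all frames; only the
    neck and the midline are extracted per frame.  This removes beat-
    phase-dependent head-pose error.  With ``consolidate_cell=False``
    every frame runs the full single-frame pipeline independently.
    """
    pose = None
    if consolidate_cell:
        try:
            pose = _pose_from_median(stack)
        except (SegmentationError, HeadError):
            pose = None
    out: list[FrameAnalysis | None] = []
    for i in range(stack.n_frames):
        try:
            if pose is not None:
                fa = _analyze_frame_with_pose(
                    stack.frames[i], stack.pixel_size_um, pose,
                    expected_area_um2, inner_d_um, outer_d_um, min_length_um)
            else:
                fa = analyze_frame(stack.frames[i], stack.pixel_size_um,
                                   expected_area_um2, inner_d_um, outer_d_um,
                                   min_length_um)
            fa.frame = i
            out.append(fa)
        except (SegmentationError, HeadError, NeckError, TraceError,
                GeometryError):
            out.append(None)
    # QC: drop frames whose midline came out much shorter than typical —
    # self-crossings of a strongly curled flagellum can truncate the
    # skeleton path, which would corrupt the midpoint-based index
    lengths = np.array([fa.trace.total_arclength_um if fa else np.nan
                        for fa in out])
    if np.isfinite(lengths).sum() >= 3:
        typical = float(np.nanmedian(lengths))
        for i, fa in enumerate(out):
            if fa is not None and fa.trace.total_arclength_um < 0.7 * typical:
                out[i] = None
    return out


def _pose_from_median(stack: ImageStack) -> CellFrame:
    """Head pose (centroid, axis, hook) from the movie's temporal median.

    In a head-tethered movie only the head is present in every frame, so
    the median image shows it at full brightness on a clean background
    while the beating flagellum (transient at any given pixel) and the
    frame noise are both suppressed.
    """
    step = max(1, stack.n_frames // 50)
    median = np.median(stack.frames[::step].astype(float), axis=0)
    sm = ndi.gaussian_filter(median, 1.0)
    bg = float(np.median(sm))
    peak = float(sm.max())
    if peak <= bg:
        raise HeadError("median image has no bright structure")
    # 4x spline upsampling gives the moment fit subpixel support (the
    # head covers only ~40 native pixels at 1 µm/px); grid_mode keeps
    # pixel i at native coordinate (i + 0.5)/4 - 0.5
    zoom = 4
    up = ndi.zoom(sm, zoom, order=3, grid_mode=True, mode="nearest")
    up_px = stack.pixel_size_um / zoom
    mask = up >= bg + 0.25 * (peak - bg)
    peak_rc = np.unravel_index(np.argmax(up), up.shape)
    hint = np.array([peak_rc[1], peak_rc[0]], dtype=float) * up_px
    pose = locate_head(mask, up_px, intensity=up, near_um=hint)
    shift = 0.5 * (stack.pixel_size_um - up_px)  # grid-mode origin offset
    return CellFrame(head_centroid_um=pose.head_centroid_um - shift,
                     head_axis_angle_rad=pose.head_axis_angle_rad,
                     hook_sign=pose.hook_sign)


def _analyze_frame_with_pose(frame: np.ndarray, pixel_size_um: float,
                             pose: CellFrame, expected_area_um2: float,
                             inner_d_um: float, outer_d_um: float,
                             min_length_um: float,
                             denoise_sigma_px: float = 1.0) -> FrameAnalysis:
    """Per-frame segmentation with a fixed (per-cell) head pose."""
    work = ndi.gaussian_filter(np.asarray(frame, dtype=float),
                               denoise_sigma_px) if denoise_sigma_px > 0 \
        else np.asarray(frame, dtype=float)
    expected_px = max(1, int(round(expected_area_um2 / pixel_size_um ** 2)))
    seg = iterative_threshold(work, expected_px)
    mask = clean_mask(seg.mask)
    neck_point, azimuth = locate_neck(mask, pose.head_centroid_um,
                                      pixel_size_um, inner_d_um, outer_d_um)
    axis, hook = pose.head_axis_angle_rad, pose.hook_sign
    if np.cos(axis - azimuth) < 0:  # orient the axis toward the neck
        axis = wrap_angle(axis + np.pi)
        hook = -hook
    cell = CellFrame(head_centroid_um=pose.head_centroid_um.copy(),
                     head_axis_angle_rad=axis, hook_sign=hook,
                     neck_point_um=neck_point, neck_azimuth_rad=azimuth)
    trace = extract_midline(mask, cell.head_centroid_um, pixel_size_um,
                            min_length_um=min_length_um,
                            trim_radius_um=inner_d_um / 2)
    return FrameAnalysis(frame=-1, segmentation=seg, cell=cell, trace=trace)


def frame_table(analyses: list[FrameAnalysis | None]) -> pd.DataFrame:
    """Per-frame segmentation summary table (NaN rows for dropped frames)."""
    rows = []
    for i, fa in enumerate(analyses):
        if fa is None:
            rows.append({"frame": i, "threshold": np.nan, "area_px": np.nan,
                         "head_x_um": np.nan, "head_y_um": np.nan,
                         "head_axis_rad": np.nan, "neck_azimuth_rad": np.nan,
                         "hook_sign": 0})
            continue
        rows.append({
            "frame": i,
            "threshold": fa.segmentation.threshold_used,
            "area_px": fa.segmentation.area_px,
            "head_x_um": fa.cell.head_centroid_um[0],
            "head_y_um": fa.cell.head_centroid_um[1],
            "head_axis_rad": fa.cell.head_axis_angle_rad,
            "neck_azimuth_rad": fa.cell.neck_azimuth_rad,
            "hook_sign": fa.cell.hook_sign,
        })
    return pd.DataFrame(rows)
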