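"""Shared geometric primitives: midline traces, per-frame cell geometry, angles.

Coordinates are (x, y) in µm with x along image columns and y along image
rows (y increases downward).  Angles are measured with ``atan2(dy, dx)``
and wrapped to (−π, π]; within this self-consistent frame "counter-
clockwise" means increasing angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["FlagellumTrace", "CellFrame", "wrap_angle", "signed_angle", "unit"]


def wrap_angle(theta: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle (rad) into (−π, π]."""
    wrapped = np.mod(np.asarray(theta) + np.pi, 2 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(wrapped)
    return wrapped


def unit(angle_rad: float) -> np.ndarray:
    """Unit vector at the given angle."""
    return np.array([np.cos(angle_rad), np.sin(angle_rad)])


def signed_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Signed angle (rad) from vector ``u`` to vector ``v`` in (−π, π]."""
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return float(np.arctan2(cross, dot))


@dataclass
class FlagellumTrace:
    """Ordered flagellar midline, proximal (neck) to distal (tip).

    ``points_um`` is an (N, 2) array of (x, y) positions in µm;
    ``arclength_um`` is the cumulative arc length along those points,
    starting at 0 for the first point.
    """

    points_um: np.ndarray
    arclength_um: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float)
        if self.points_um.ndim != 2 or self.points_um.shape[1] != 2:
            raise ParameterError("points_um must be an (N, 2) array")
        if self.points_um.shape[0] < 2:
            raise ParameterError("a trace needs at least 2 points")
        if self.arclength_um is None:
            seg = np.linalg.norm(np.diff(self.points_um, axis=0), axis=1)
            self.arclength_um = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.arclength_um = np.asarray(self.arclength_um, dtype=float)
        if np.any(np.diff(self.arclength_um) <= 0):
            raise ParameterError("arclength must be strictly increasing")

    @property
    def total_arclength_um(self) -> float:
        return float(self.arclength_um[-1])

    def point_at_arclength(self, s_um: float) -> np.ndarray:
        """Linearly interpolated (x, y) at arc length ``s_um`` (clamped)."""
        s = float(np.clip(s_um, 0.0, self.total_arclength_um))
        x = np.interp(s, self.arclength_um, self.points_um[:, 0])
        y = np.interp(s, self.arclength_um, self.points_um[:, 1])
        return np.array([x, y])

    def midpoint(self) -> np.ndarray:
        """Point at 50% of the total arc length ("middle of the flagellum")."""
        return self.point_at_arclength(0.5 * self.total_arclength_um)


@dataclass
class CellFrame:
    """Per-frame cell geometry: head pose, neck location, hook side.

    ``head_axis_angle_rad`` is the cell symmetry axis, oriented tail-ward
    (from the head centroid through the neck).  ``hook_sign`` is +1 when
    the head hook bulges toward the left-normal of that axis, −1 for the
    other side.  Neck fields are ``None`` until the neck has been located.
    """

    head_centroid_um: np.ndarray
    head_axis_angle_rad: float
    hook_sign: int
    neck_point_um: np.ndarray | None = None
    neck_azimuth_rad: float | None = None

    def __post_init__(self) -> None:
        self.head_centroid_um = np.asarray(self.head_centroid_um, dtype=float)
        if abs(self.hook_sign) != 1:
            raise ParameterError("hook_sign must be +1 or -1")
        self.head_axis_angle_rad = wrap_angle(self.head_axis_angle_rad)
        if self.neck_point_um is not None:
            self.neck_point_um = np.asarray(self.neck_point_um, dtype=float)
        if self.neck_azimuth_rad is not None:
            self.neck_azimuth_rad = wrap_angle(self.neck_azimuth_rad)

    def axis_unit(self) -> np.ndarray:
        return unit(self.head_axis_angle_rad)
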