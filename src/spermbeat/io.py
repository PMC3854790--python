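"""Containers and file I/O for image stacks, stage logs and metric tables.

Movies are multi-page grayscale TIFF stacks; stage logs, fluorescence
traces and per-frame metrics are plain CSV; ground truth and run summaries
are JSON.  All geometry leaving this module is in micrometres: image
row/column maps to (y, x) µm with the origin at the top-left corner and y
increasing downward; angles are radians, counter-clockwise positive in that
(x, y) frame.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError

__all__ = [
    "ImageStack",
    "StageLog",
    "read_stack",
    "write_stack",
    "read_stage_log",
    "write_stage_log",
    "write_metrics",
    "read_metrics",
    "write_json",
    "read_json",
]


@dataclass
class ImageStack:
    """A time-lapse grayscale movie with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``; integer or float
        intensities.
    fps
        Acquisition frame rate in frames per second.
    pixel_size_um
        Physical size of one pixel in µm.
    flash_frame
        Optional index of the first frame after a UV flash; analysis
        windows never cross it.
    """

    frames: np.ndarray
    fps: float
    pixel_size_um: float
    flash_frame: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError("stack must be (n_frames, height, width) with >= 1 frame")
        if self.fps <= 0:
            raise FormatError("fps must be positive")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class StageLog:
    """Per-frame motorized-stage offsets in µm (one row per movie frame)."""

    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.x_um.shape != self.y_um.shape or self.x_um.ndim != 1:
            raise FormatError("stage log x/y must be equal-length 1-D arrays")

    def __len__(self) -> int:
        return int(self.x_um.size)

    @classmethod
    def zeros(cls, n: int) -> "StageLog":
        return cls(np.zeros(n), np.zeros(n))


def read_stack(path: str | Path, fps: float, pixel_size_um: float,
               flash_frame: int | None = None) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    8-bit, 16-bit and float pages are accepted; RGB pages are rejected.
    ``fps`` and ``pixel_size_um`` come from the caller (config or sidecar)
    because plain TIFFs carry no reliable acquisition metadata.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected grayscale pages, got shape {data.shape}")
    return ImageStack(data, fps=fps, pixel_size_um=pixel_size_um, flash_frame=flash_frame)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as a multi-page TIFF; pixel values round-trip exactly."""
    tifffile.imwrite(Path(path), stack.frames, photometric="minisblack")


def read_stage_log(path: str | Path) -> StageLog:
    """Read a stage log CSV with columns ``frame,x_um,y_um``."""
    df = pd.read_csv(path)
    for col in ("frame", "x_um", "y_um"):
        if col not in df.columns:
            raise FormatError(f"stage log {path} missing column {col!r}")
    df = df.sort_values("frame")
    return StageLog(df["x_um"].to_numpy(), df["y_um"].to_numpy())


def write_stage_log(path: str | Path, log: StageLog) -> None:
    pd.DataFrame({
        "frame": np.arange(len(log)),
        "x_um": log.x_um,
        "y_um": log.y_um,
    }).to_csv(path, index=False)


def write_metrics(path: str | Path, table: pd.DataFrame) -> None:
    """Write a per-frame metrics table as CSV."""
    table.to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
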