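"""Exception hierarchy for the analysis pipeline.

Every failure mode that downstream code is expected to catch and handle
(dropped frames, lost tracks, undefined indices) raises a subclass of
:class:`SpermBeatError`, so callers can distinguish analysis failures from
programming errors.
"""


class SpermBeatError(Exception):
    """Base class for all analysis-level failures."""


class ParameterError(SpermBeatError, ValueError):
    """Invalid physical or rendering parameters."""


class GeometryError(SpermBeatError):
    """Cell geometry does not fit the requested image."""


class SegmentationError(SpermBeatError):
    """Thresholding could not reach the expected foreground area.

    Carries ``last_area`` — the foreground area at the lowest threshold
    tried — for diagnostics.
    """

    def __init__(self, message: str, last_area: int | None = None):
        super().__init__(message)
        self.last_area = last_area


class TraceError(SpermBeatError):
    """Skeleton/midline extraction failed (e.g. skeleton too short)."""


class HeadError(SpermBeatError):
    """No head-like region found in the mask."""


class NeckError(SpermBeatError):
    """No foreground pixels inside the neck annulus."""


class UndefinedIndexError(SpermBeatError):
    """Asymmetry index undefined (degenerate trace geometry)."""


class MissingValueError(SpermBeatError):
    """A windowed statistic has no valid frames to average."""


class TrackLostError(SpermBeatError):
    """Head registration lost the cell for too many consecutive frames."""


class NormalizationError(SpermBeatError):
    """Baseline normalization impossible (non-positive baseline)."""


class CalibrationRangeError(SpermBeatError):
    """Null-point calibration: fluorescence change never crosses zero."""


class AlignmentError(SpermBeatError):
    """Envelope superposition had no valid frames."""


class FormatError(SpermBeatError):
    """Unreadable or unsupported input file."""
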