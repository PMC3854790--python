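"""Fluorescence-trace normalization and null-point Ca²⁺ calibration.

Covers the photometry used around flash experiments: background-subtracted
F/F₀ normalization of single-channel traces, donor/acceptor ratio traces
normalized to their pre-event mean, and the null-point estimate of resting
intracellular Ca²⁺ (the clamp concentration at which ionophore
permeabilization produces no fluorescence change).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationRangeError, FormatError, NormalizationError

__all__ = [
    "FluorescenceTrace",
    "RatioTrace",
    "CalibrationSeries",
    "normalize_to_baseline",
    "fret_ratio",
    "nullpoint_calibrate",
    "read_trace_csv",
    "read_ratio_csv",
    "read_calibration_csv",
]


@dataclass
class FluorescenceTrace:
    """Single-channel fluorescence time series with an event marker.

    ``background`` may be a scalar, a per-sample array, or ``None`` (no
    subtraction).  ``event_frame`` is the index of the first sample after
    the event (flash / perfusion start); samples before it are baseline.
    """

    time_s: np.ndarray
    raw: np.ndarray
    background: float | np.ndarray | None = None
    event_frame: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.time_s.shape != self.raw.shape:
            raise FormatError("time_s and raw must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise FormatError("timestamps must be strictly increasing")
        if isinstance(self.background, np.ndarray) and \
                self.background.shape != self.raw.shape:
            raise FormatError("per-sample background must match raw length")


@dataclass
class RatioTrace:
    """Two-channel (donor, acceptor) trace for ratiometric reporters."""

    time_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    event_frame: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.time_s.shape == self.donor.shape == self.acceptor.shape):
            raise FormatError("channels and timestamps must have equal length")
        if np.any(self.donor < 0) or np.any(self.acceptor < 0):
            raise FormatError("channel intensities must be >= 0")


@dataclass
class CalibrationSeries:
    """Fluorescence change Δ per clamp Ca²⁺ concentration (nM, ascending)."""

    ca_nm: np.ndarray
    delta_f: np.ndarray

    def __post_init__(self) -> None:
        self.ca_nm = np.asarray(self.ca_nm, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        if self.ca_nm.shape != self.delta_f.shape or self.ca_nm.size < 2:
            raise FormatError("calibration needs >= 2 matched points")
        if np.any(np.diff(self.ca_nm) <= 0):
            raise FormatError("concentrations must be strictly increasing")
        if np.any(self.ca_nm <= 0):
            raise FormatError("concentrations must be positive")


def normalize_to_baseline(trace: FluorescenceTrace) -> np.ndarray:
    """Background-subtracted F/F₀ normalized to the pre-event mean.

    Returns (raw − background) divided by its mean over the samples before
    ``event_frame``; the pre-event mean of the output is exactly 1.  The
    operation is idempotent: applying it to an already-normalized trace is
    the identity.
    """
    if trace.event_frame < 1:
        raise NormalizationError("need at least one pre-event sample")
    corrected = trace.raw - (0.0 if trace.background is None else trace.background)
    baseline = float(np.mean(corrected[:trace.event_frame]))
    if baseline <= 0:
        raise NormalizationError(f"non-positive baseline ({baseline:g})")
    return corrected / baseline


def fret_ratio(trace: RatioTrace) -> np.ndarray:
    """Donor/acceptor ratio normalized to its pre-event mean."""
    if trace.event_frame < 1:
        raise NormalizationError("need at least one pre-event sample")
    if np.any(trace.acceptor <= 0):
        raise NormalizationError("acceptor channel has non-positive samples")
    r = trace.donor / trace.acceptor
    baseline = float(np.mean(r[:trace.event_frame]))
    if baseline <= 0:
        raise NormalizationError("non-positive pre-event ratio")
    return r / baseline


def nullpoint_calibrate(series: CalibrationSeries,
                        log_interp: bool = True) -> float:
    """Resting [Ca²⁺]ᵢ (nM) from a null-point series.

    The estimate is the concentration at which the fluorescence change Δ
    crosses zero: returned exactly if some Δ = 0, otherwise interpolated
    between the bracketing concentrations — in log concentration by
    default (indicator responses are approximately log-linear), linearly
    with ``log_interp=False``.
    """
    d = series.delta_f
    zero = np.flatnonzero(d == 0)
    if zero.size:
        return float(series.ca_nm[zero[0]])
    sign_change = np.flatnonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)
    if not sign_change.size:
        raise CalibrationRangeError(
            "fluorescence change never crosses zero; resting [Ca2+]i lies "
            f"outside [{series.ca_nm[0]:g}, {series.ca_nm[-1]:g}] nM")
    i = int(sign_change[0])
    c0, c1 = series.ca_nm[i], series.ca_nm[i + 1]
    frac = -d[i] / (d[i + 1] - d[i])
    if log_interp:
        return float(10 ** (np.log10(c0) + frac * (np.log10(c1) - np.log10(c0))))
    return float(c0 + frac * (c1 - c0))


def read_trace_csv(path: str | Path, event_frame: int = 0) -> FluorescenceTrace:
    """Read a trace CSV with columns ``time_s,raw`` and optional ``background``."""
    df = pd.read_csv(path)
    bg = df["background"].to_numpy() if "background" in df.columns else None
    return FluorescenceTrace(df["time_s"].to_numpy(), df["raw"].to_numpy(),
                             background=bg, event_frame=event_frame)


def read_ratio_csv(path: str | Path, event_frame: int = 0) -> RatioTrace:
    df = pd.read_csv(path)
    return RatioTrace(df["time_s"].to_numpy(), df["donor"].to_numpy(),
                      df["acceptor"].to_numpy(), event_frame=event_frame)


def read_calibration_csv(path: str | Path) -> CalibrationSeries:
    df = pd.read_csv(path)
    return CalibrationSeries(df["ca_nM"].to_numpy(), df["delta_f"].to_numpy())
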