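"""Shared containers and exceptions for the PPG-ECG coupling pipeline.

The carrier type for every signal in the pipeline is :class:`TimeSeries`, a
uniformly sampled waveform with an explicit sampling rate and start time.
Per-beat ground truth (from the simulator) travels as :class:`BeatAnnotation`
lists; detection output travels as :class:`FiducialSet`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "BeatAnnotation",
    "RPeakList",
    "FiducialSet",
    "BeatFeatures",
    "SubjectRecord",
    "PpgEcgError",
    "InvalidAnnotationError",
    "ConfigurationError",
    "AlignmentError",
    "DegenerateSignalError",
    "SignalLengthError",
    "FormatError",
    "SchemaError",
]


class PpgEcgError(Exception):
    """Base class for all pipeline errors."""


class InvalidAnnotationError(PpgEcgError):
    """Beat times violate ordering or physiological constraints."""


class ConfigurationError(PpgEcgError):
    """A parameter set is internally inconsistent."""


class AlignmentError(PpgEcgError):
    """Two signals that must share a time base do not."""


class DegenerateSignalError(PpgEcgError):
    """A signal carries no measurable structure (e.g. flat ECG)."""


class SignalLengthError(PpgEcgError):
    """A signal is too short for the requested operation."""


class FormatError(PpgEcgError):
    """An on-disk artifact does not parse as expected."""


class SchemaError(PpgEcgError):
    """A feature table is missing fields the model was trained on."""


@dataclass
class TimeSeries:
    """Uniformly sampled waveform.

    Parameters
    ----------
    samples:
        Amplitude values, arbitrary units.
    fs:
        Sampling rate in Hz.
    t0:
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ConfigurationError("TimeSeries samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("TimeSeries samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the record)."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.samples.size - 1)

    def time_of(self, i: int) -> float:
        return self.t0 + i / self.fs

    def copy(self) -> "TimeSeries":
        return TimeSeries(self.samples.copy(), self.fs, self.t0)


@dataclass(frozen=True)
class BeatAnnotation:
    """Ground-truth landmark times for one cardiac cycle (seconds)."""

    r_time: float
    onset_time: float
    peak_time: float

    def __post_init__(self) -> None:
        if not (self.r_time < self.onset_time < self.peak_time):
            raise InvalidAnnotationError(
                f"landmarks out of order: R={self.r_time}, "
                f"onset={self.onset_time}, peak={self.peak_time}"
            )

    @property
    def ptt(self) -> float:
        return self.onset_time - self.r_time


@dataclass
class RPeakList:
    """Detected R-wave locations on one ECG record."""

    r_indices: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        if self.r_indices.size and np.any(np.diff(self.r_indices) <= 0):
            raise InvalidAnnotationError("R indices must be strictly increasing")

    @property
    def r_times(self) -> np.ndarray:
        return self.t0 + self.r_indices / self.fs

    def __len__(self) -> int:
        return self.r_indices.size


# Sentinel for a landmark the detector could not place.
MISSING = float("nan")


@dataclass
class FiducialSet:
    """Per-beat landmark times from one detection method.

    ``onset_times`` / ``peak_times`` use NaN for landmarks flagged MISSING.
    ``r_times`` / ``next_r_times`` are NaN for the PPG-only baselines, which
    never see the ECG channel.
    """

    onset_times: np.ndarray
    peak_times: np.ndarray
    source_method: str
    r_times: np.ndarray | None = None
    next_r_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.r_times is not None:
            self.r_times = np.asarray(self.r_times, dtype=float)
        if self.next_r_times is not None:
            self.next_r_times = np.asarray(self.next_r_times, dtype=float)

    def __len__(self) -> int:
        return self.onset_times.size

    def detected_onsets(self) -> np.ndarray:
        return self.onset_times[np.isfinite(self.onset_times)]

    def detected_peaks(self) -> np.ndarray:
        return self.peak_times[np.isfinite(self.peak_times)]


@dataclass(frozen=True)
class BeatFeatures:
    """Per-beat derived quantities feeding the BP model.

    ``t_sys`` is the onset-to-systolic-peak rise time, the interval commonly
    written T in the PTT literature.
    """

    r_time: float
    rr: float
    ptt: float
    pir: float
    t_sys: float

    def __post_init__(self) -> None:
        if not (self.rr > 0 and self.ptt > 0 and self.pir > 0 and self.t_sys > 0):
            raise InvalidAnnotationError("beat features must be strictly positive")
        if self.ptt >= self.rr:
            raise InvalidAnnotationError(f"PTT {self.ptt} must be < RR {self.rr}")


@dataclass
class SubjectRecord:
    """Signals, demographics, and reference BP for one simulated subject."""

    subject_id: str
    sex: str  # "M" or "F"
    age: float  # years
    weight: float  # kg
    ecg: TimeSeries
    ppg: TimeSeries
    truth: list[BeatAnnotation]
    bp_ref: list[tuple[float, float, float]]  # (time_s, sbp_mmHg, dbp_mmHg)
    truth_features: "object | None" = None  # per-window truth feature table

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ConfigurationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if abs(self.ecg.fs - self.ppg.fs) > 1e-9 or len(self.ecg) != len(self.ppg):
            raise AlignmentError("ECG and PPG must share fs and length")
        r = [a.r_time for a in self.truth]
        if any(b <= a for a, b in zip(r, r[1:])):
            raise InvalidAnnotationError("annotation times must be strictly increasing")
        for _, sbp, dbp in self.bp_ref:
            if sbp <= dbp:
                raise InvalidAnnotationError(f"SBP {sbp} must exceed DBP {dbp}")
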