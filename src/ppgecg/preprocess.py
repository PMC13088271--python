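"""Filtering and amplitude conditioning applied before signal coupling.

Both channels pass through a zero-phase 0.5-40 Hz bandpass (4th-order
Butterworth run forward-backward), after which the PPG is rescaled so its
robust amplitude is about twice the ECG R amplitude - the ratio at which
both signals' features stay legible in the coupled waveform.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import ConfigurationError, DegenerateSignalError, SignalLengthError, TimeSeries

__all__ = ["bandpass_zero_phase", "scale_for_coupling", "robust_amplitudes"]

_ORDER = 4


def bandpass_zero_phase(
    ts: TimeSeries, low_hz: float = 0.5, high_hz: float = 40.0
) -> TimeSeries:
    """Forward-backward Butterworth bandpass; no phase distortion.

    Edges are handled by ~1 s of reflect padding (scipy's odd extension) to
    suppress filtfilt transients on short records.
    """
    if not (0 < low_hz < high_hz):
        raise ConfigurationError(f"need 0 < low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= ts.fs / 2:
        raise ConfigurationError(
            f"high_hz {high_hz} must be below the Nyquist frequency {ts.fs / 2}"
        )
    sos = sps.butter(_ORDER, [low_hz, high_hz], btype="bandpass", fs=ts.fs, output="sos")
    padlen = min(int(ts.fs), len(ts) - 2)
    if padlen < 3 * _ORDER:
        raise SignalLengthError(f"series of {len(ts)} samples is too short to filter")
    y = sps.sosfiltfilt(sos, ts.samples, padlen=padlen)
    return TimeSeries(y, ts.fs, ts.t0)


def robust_amplitudes(
    ppg: TimeSeries, ecg: TimeSeries, min_beat_s: float = 0.3
) -> tuple[float, float]:
    """Median per-beat PPG peak-to-trough span and median ECG R height."""
    dist = max(1, int(min_beat_s * ppg.fs))
    p = ppg.samples
    peaks, _ = sps.find_peaks(p, distance=dist)
    troughs, _ = sps.find_peaks(-p, distance=dist)
    if peaks.size and troughs.size:
        ppg_span = float(np.median(p[peaks]) - np.median(p[troughs]))
    else:
        ppg_span = float(np.ptp(p))
    e = ecg.samples
    if np.ptp(e) == 0:
        raise DegenerateSignalError("flat ECG: no measurable R amplitude")
    rdist = max(1, int(0.25 * ecg.fs))
    cand, _ = sps.find_peaks(e, distance=rdist, height=0.5 * np.max(e))
    if cand.size == 0:
        raise DegenerateSignalError("no R-like peaks found in ECG")
    r_amp = float(np.median(e[cand]))
    if r_amp <= 0:
        raise DegenerateSignalError("ECG R amplitude is not positive")
    return ppg_span, r_amp


def scale_for_coupling(
    ppg: TimeSeries, ecg: TimeSeries, target_ratio: float = 2.0
) -> TimeSeries:
    """Rescale the PPG so robust PPG amplitude / ECG R amplitude = target.

    Idempotent: a PPG already at the target ratio comes back with a scale
    factor of 1.
    """
    if abs(ppg.fs - ecg.fs) > 1e-9:
        raise ConfigurationError("PPG and ECG must share a sampling rate")
    ppg_span, r_amp = robust_amplitudes(ppg, ecg)
    if ppg_span <= 0:
        raise DegenerateSignalError("flat PPG: nothing to scale")
    scale = target_ratio * r_amp / ppg_span
    return TimeSeries(ppg.samples * scale, ppg.fs, ppg.t0)
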