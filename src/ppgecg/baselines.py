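"""Individual-signal comparator methods: PPG-only fiducial detection.

Two established single-channel approaches serve as comparators for the
coupled method: local-extrema detection with an adaptive amplitude threshold
(no R-wave anchoring), and adaptive first-derivative analysis. By interface
neither sees the ECG channel. Both are parameter-transparent reconstructions
of the standard algorithms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d

from .core import FiducialSet, RPeakList, TimeSeries

__all__ = [
    "LocalExtremaParams",
    "DerivativeParams",
    "detect_local_extrema",
    "detect_derivative",
    "pair_ptt",
]


@dataclass(frozen=True)
class LocalExtremaParams:
    min_peak_dist_s: float = 0.3
    amp_frac: float = 0.5  # accept peaks above amp_frac * rolling 75th pct
    roll_n: int = 10  # number of trailing peaks in the rolling statistic
    lookback_s: float = 0.5  # onset search window before each peak


@dataclass(frozen=True)
class DerivativeParams:
    deriv_frac: float = 0.4  # accept upstrokes above deriv_frac * rolling max
    roll_window_s: float = 2.0
    refractory_s: float = 0.3
    onset_mode: str = "zero_cross"  # or "d2max"
    lookback_s: float = 0.3


def detect_local_extrema(
    ppg: TimeSeries, params: LocalExtremaParams | None = None
) -> FiducialSet:
    """Systolic peaks as thresholded local maxima; onsets as preceding minima.

    The amplitude threshold adapts as a fraction of the rolling 75th
    percentile of recent peak heights, which is what makes the method lose
    alternating low-amplitude pulses - the failure mode R anchoring avoids.
    """
    p = params or LocalExtremaParams()
    x = ppg.samples
    dist = max(1, int(p.min_peak_dist_s * ppg.fs))
    cand, _ = sps.find_peaks(x, distance=dist)
    onsets: list[float] = []
    pks: list[float] = []
    recent: list[float] = []
    look = int(p.lookback_s * ppg.fs)
    for ci in cand:
        h = x[ci]
        ref = np.percentile(recent[-p.roll_n:], 75) if recent else h
        if h >= p.amp_frac * ref:
            lo = max(0, ci - look)
            oi = lo + int(np.argmin(x[lo:ci])) if ci > lo else ci
            onsets.append(ppg.time_of(oi))
            pks.append(ppg.time_of(ci))
            recent.append(h)
    return FiducialSet(
        onset_times=np.asarray(onsets),
        peak_times=np.asarray(pks),
        source_method="local_extrema",
    )


def detect_derivative(
    ppg: TimeSeries, params: DerivativeParams | None = None
) -> FiducialSet:
    """Upstroke detection on the first derivative with an adaptive threshold.

    Candidate upstrokes are runs where d/dt exceeds a fraction of its rolling
    maximum; each accepted upstroke yields the onset (preceding zero-crossing
    of the derivative, or the second-derivative maximum, by ``onset_mode``)
    and the systolic peak (next positive-to-negative derivative crossing).
    """
    p = params or DerivativeParams()
    x = ppg.samples
    fs = ppg.fs
    d = np.gradient(x) * fs
    if np.ptp(d) == 0:
        return FiducialSet(np.empty(0), np.empty(0), "derivative")
    win = max(3, int(p.roll_window_s * fs))
    rolmax = maximum_filter1d(np.maximum(d, 0), size=win)
    thr = p.deriv_frac * np.maximum(rolmax, 1e-12)
    above = d > thr
    # Run starts of supra-threshold stretches.
    starts = np.flatnonzero(above & ~np.roll(above, 1))
    if above.size and above[0]:
        starts = np.unique(np.append(starts, 0))
    refractory = int(p.refractory_s * fs)
    look = int(p.lookback_s * fs)
    onsets: list[float] = []
    pks: list[float] = []
    last = -refractory
    d2 = np.gradient(d) * fs
    for s in starts:
        if s - last < refractory:
            continue
        lo = max(0, s - look)
        seg = d[lo: s + 1]
        if p.onset_mode == "d2max":
            oi = lo + int(np.argmax(d2[lo: s + 1]))
        else:
            neg = np.flatnonzero(seg <= 0)
            oi = lo + int(neg[-1]) if neg.size else lo
        # Systolic peak: next downward zero-crossing of the derivative.
        rest = d[s:]
        crossing = np.flatnonzero(rest <= 0)
        if crossing.size == 0:
            continue
        pi = s + int(crossing[0])
        if pi <= oi:
            continue
        onsets.append(ppg.time_of(oi))
        pks.append(ppg.time_of(pi))
        last = s
    return FiducialSet(
        onset_times=np.asarray(onsets),
        peak_times=np.asarray(pks),
        source_method="derivative",
    )


def pair_ptt(
    peaks: RPeakList,
    fid: FiducialSet,
    max_lag_s: float | None = None,
    max_lag_frac: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy first-match pairing of R waves with detected onsets.

    Each R is paired with the first unclaimed onset in (R, R + lag], where
    lag is ``max_lag_s`` or ``max_lag_frac`` times the local RR interval.
    Returns (ptt_s per R, NaN when unpaired; paired mask; detection_rate).
    This mirrors the failure mode of single-channel detection: a missed
    onset leaves its R unpaired or steals the next beat's onset.
    """
    r = peaks.r_times
    onsets = np.sort(fid.detected_onsets())
    ptt = np.full(r.size, np.nan)
    claimed = np.zeros(onsets.size, dtype=bool)
    rr = np.diff(r)
    med_rr = float(np.median(rr)) if rr.size else 1.0
    for k in range(r.size):
        lag = max_lag_s if max_lag_s is not None else max_lag_frac * (
            rr[k] if k < rr.size else med_rr
        )
        j = np.searchsorted(onsets, r[k], side="right")
        while j < onsets.size and claimed[j]:
            j += 1
        if j < onsets.size and onsets[j] <= r[k] + lag:
            claimed[j] = True
            ptt[k] = onsets[j] - r[k]
    paired = np.isfinite(ptt)
    rate = float(paired.mean()) if r.size else 0.0
    return ptt, paired, rate
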