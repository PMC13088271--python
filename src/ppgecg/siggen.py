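"""Seeded generator of paired ECG/PPG waveforms with ground-truth annotations.

Stands in for volunteer chest recordings: a beat train with controllable heart
rate and variability, an ECG rendered as a five-bump (P,Q,R,S,T) Gaussian
template, a PPG pulse rendered as a monotone spline through physiologic control
points (foot, systolic peak, dicrotic notch, dicrotic wave, diastolic decay),
a known per-beat R-to-onset lag (the PTT), additive noise (baseline wander,
broadband Gaussian, motion artifacts), and an explicit generative BP-feature
relationship for parameter-recovery experiments.

The spline pulse places its unique interior minimum exactly at the annotated
pulse foot and its maximum exactly at the annotated systolic peak, so on
zero-noise signals every downstream fiducial is recoverable to the sample.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .core import (
    BeatAnnotation,
    ConfigurationError,
    InvalidAnnotationError,
    SubjectRecord,
    TimeSeries,
)

__all__ = [
    "SimConfig",
    "MORPHOLOGY_PRESETS",
    "SBP_COEFFS",
    "DBP_COEFFS",
    "generate_beat_train",
    "synthesize_ecg",
    "synthesize_ppg",
    "beat_annotations",
    "add_noise",
    "generate_bp_truth",
    "generate_subject",
    "generate_cohort",
]

# ECG template: per-wave (offset_s relative to R, width_s, amplitude).
_ECG_WAVES = (
    (-0.200, 0.030, 0.12),  # P
    (-0.028, 0.010, -0.08),  # Q
    (0.000, 0.012, 1.00),  # R
    (0.030, 0.011, -0.18),  # S
    (0.220, 0.050, 0.28),  # T
)

# Interval truncation bounds for the beat train (seconds).
_RR_MIN, _RR_MAX = 0.3, 2.0

# Optical DC baseline (in units of normalized pulse amplitude) used when
# forming the ground-truth PPG intensity ratio: real PPG rides on a large
# perfusion baseline, so PIR = (dc + peak amp) / (dc + foot amp).
_PPG_DC = 2.0


class SimConfig(BaseModel):
    """Simulation conditions for one subject recording."""

    model_config = ConfigDict(extra="forbid")

    duration_s: float = 120.0
    fs: float = 500.0
    hr_mean: float = 75.0  # beats/min
    hr_sd: float = 5.0  # beats/min
    ptt_mean: float = 0.20  # s, R wave to pulse foot
    ptt_sd: float = 0.012  # s, beat-to-beat jitter
    ptt_drift_amp: float = 0.02  # s, slow within-record PTT swing
    ptt_drift_period_s: float = 60.0
    amp_ratio: float = 2.0  # target PPG:ECG amplitude ratio after scaling
    noise_baseline_amp: float = 0.10  # fraction of signal amplitude
    noise_gauss_sd: float = 0.03  # fraction of signal amplitude
    artifact_rate: float = 1.0  # events/min, seated-rest acquisition
    # Pulse morphology knobs (the presets below vary these).
    t_sys: float = 0.15  # s, foot-to-systolic-peak rise time
    notch_depth: float = 0.45  # dicrotic notch level, fraction of pulse amp
    dicrotic_prominence: float = 0.10  # dicrotic wave height above the notch
    # Respiratory amplitude modulation of the pulse train: chest PPG shows
    # marked breath-by-breath envelope swings, the signal variety that makes
    # un-anchored fiducial detection hard in the first place.
    amp_mod_depth: float = 0.25
    amp_mod_period_s: float = 4.0  # ~15 breaths/min
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs < 100:
            raise ValueError("fs must be at least 100 Hz")
        if not 30 <= self.hr_mean <= 200:
            raise ValueError("hr_mean must lie in [30, 200] bpm")
        if not 0 < self.ptt_mean < 60.0 / self.hr_mean:
            raise ValueError("ptt_mean must lie in (0, mean RR)")
        for name in ("hr_sd", "ptt_sd", "noise_baseline_amp", "noise_gauss_sd",
                     "artifact_rate", "ptt_drift_amp", "amp_mod_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.notch_depth < 1:
            raise ValueError("notch_depth must lie in (0, 1)")
        if self.notch_depth + self.dicrotic_prominence >= 1:
            raise ValueError("dicrotic wave must stay below the systolic peak")
        return self


#: Pulse-shape presets spanning the waveform variety the coupling method must
#: tolerate: narrow/wide pulses, strong/damped dicrotic waves, and
#: beat-to-beat amplitude modulation.
MORPHOLOGY_PRESETS: dict[str, dict[str, float]] = {
    "default": {},
    "narrow_pulse": {"t_sys": 0.11},
    "wide_pulse": {"t_sys": 0.20},
    "prominent_dicrotic": {"notch_depth": 0.38, "dicrotic_prominence": 0.24},
    "damped_dicrotic": {"dicrotic_prominence": 0.02},
    "steady_amplitude": {"amp_mod_depth": 0.0},
    "amplitude_modulated": {"amp_mod_depth": 0.45, "amp_mod_period_s": 8.0},
}


def _rng_for(cfg: SimConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per generation stage."""
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def generate_beat_train(cfg: SimConfig) -> np.ndarray:
    """Strictly increasing R-wave times (s), snapped to the sample grid.

    Inter-beat intervals are truncated-normal with mean 60/hr_mean and the
    standard deviation implied by hr_sd (delta method: sd_RR = hr_sd * 60 /
    hr_mean^2), truncated to [0.3, 2.0] s.
    """
    rng = _rng_for(cfg, 0)
    mu = 60.0 / cfg.hr_mean
    sd = cfg.hr_sd * 60.0 / cfg.hr_mean**2
    t = 0.5  # room for the P wave of the first beat
    tail = 0.25  # room for the T wave of the last beat
    r_times: list[float] = []
    if t > cfg.duration_s - tail:
        return np.empty(0)
    while t <= cfg.duration_s - tail:
        r_times.append(round(t * cfg.fs) / cfg.fs)  # snap to grid
        if sd == 0:
            iv = float(np.clip(mu, _RR_MIN, _RR_MAX))
        else:
            a, b = (_RR_MIN - mu) / sd, (_RR_MAX - mu) / sd
            iv = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
        t += iv
    return np.asarray(r_times)


def _n_samples(cfg: SimConfig) -> int:
    return int(round(cfg.duration_s * cfg.fs))


def synthesize_ecg(r_times: np.ndarray, cfg: SimConfig) -> TimeSeries:
    """Noise-free ECG: P,Q,R,S,T Gaussian bumps per beat, max |amp| = 1."""
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size and np.any(np.diff(r_times) <= 0):
        raise InvalidAnnotationError("r_times must be strictly increasing")
    n = _n_samples(cfg)
    x = np.zeros(n)
    if r_times.size == 0:
        return TimeSeries(x, cfg.fs)
    t = np.arange(n) / cfg.fs
    for off, w, amp in _ECG_WAVES:
        for r in r_times:
            c = r + off
            lo = max(0, int((c - 5 * w) * cfg.fs))
            hi = min(n, int((c + 5 * w) * cfg.fs) + 1)
            if lo < hi:
                x[lo:hi] += amp * np.exp(-((t[lo:hi] - c) ** 2) / (2 * w * w))
    peak = np.max(np.abs(x))
    if peak > 0:
        x /= peak
    return TimeSeries(x, cfg.fs)


def _draw_ptts(r_times: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Per-beat R-to-foot lag: mean + slow drift + truncated jitter."""
    rng = _rng_for(cfg, 1)
    n = r_times.size
    if n == 0:
        return np.empty(0)
    rr = np.diff(r_times)
    rr = np.append(rr, rr[-1] if rr.size else 60.0 / cfg.hr_mean)
    drift = cfg.ptt_drift_amp * np.sin(
        2 * np.pi * r_times / cfg.ptt_drift_period_s + 0.7
    )
    ptts = cfg.ptt_mean + drift
    if cfg.ptt_sd > 0:
        ptts = ptts + rng.normal(0.0, cfg.ptt_sd, size=n)
    return np.clip(ptts, 0.05, 0.9 * rr)


def _pulse_knots(length: float, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """PCHIP control points for one pulse of unit amplitude on [0, length]."""
    tp = min(cfg.t_sys, 0.4 * length)
    tn = tp + 0.30 * (length - tp)  # dicrotic notch
    td = tp + 0.45 * (length - tp)  # dicrotic wave
    tm = tp + 0.70 * (length - tp)  # diastolic decay, mostly complete here
    tq = tp + 0.90 * (length - tp)  # end-diastolic near-baseline plateau
    tau = np.array([0.0, 0.4 * tp, tp, tn, td, tm, tq, length])
    val = np.array(
        [0.0, 0.42, 1.0, cfg.notch_depth,
         cfg.notch_depth + cfg.dicrotic_prominence, 0.10, 0.04, 0.0]
    )
    return tau, val


def _beat_amplitudes(onset_times: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.amp_mod_depth == 0:
        return np.ones_like(onset_times)
    return 1.0 + cfg.amp_mod_depth * np.sin(
        2 * np.pi * onset_times / cfg.amp_mod_period_s
    )


def beat_annotations(
    r_times: np.ndarray, ptt_per_beat: np.ndarray, cfg: SimConfig
) -> list[BeatAnnotation]:
    """Ground-truth landmarks implied by the pulse construction."""
    r_times = np.asarray(r_times, dtype=float)
    ptts = np.asarray(ptt_per_beat, dtype=float)
    _validate_ptts(r_times, ptts)
    onsets = r_times + ptts
    seg_lengths = _segment_lengths(onsets)
    out = []
    for r, o, L in zip(r_times, onsets, seg_lengths):
        tp = min(cfg.t_sys, 0.4 * L)
        out.append(BeatAnnotation(r_time=r, onset_time=o, peak_time=o + tp))
    return out


def _validate_ptts(r_times: np.ndarray, ptts: np.ndarray) -> None:
    if r_times.size != ptts.size:
        raise InvalidAnnotationError("one PTT value required per beat")
    if r_times.size and np.any(np.diff(r_times) <= 0):
        raise InvalidAnnotationError("r_times must be strictly increasing")
    rr = np.diff(r_times)
    if np.any(ptts <= 0):
        raise InvalidAnnotationError("all PTT values must be positive")
    if rr.size and np.any(ptts[:-1] >= rr):
        raise InvalidAnnotationError("each PTT must be smaller than its RR interval")


def _segment_lengths(onsets: np.ndarray) -> np.ndarray:
    """Inter-onset spans; the last beat reuses the median span."""
    if onsets.size == 0:
        return np.empty(0)
    if onsets.size == 1:
        return np.array([0.8])
    d = np.diff(onsets)
    return np.append(d, np.median(d))


def synthesize_ppg(
    r_times: np.ndarray, ptt_per_beat: np.ndarray, cfg: SimConfig
) -> TimeSeries:
    """Noise-free PPG with the pulse foot of beat k at r_times[k] + ptt[k].

    Each inter-onset segment is a monotone PCHIP spline rising from zero at
    the foot to the systolic peak, through notch and dicrotic wave, and
    decaying back to zero at the next foot, so the foot is the unique local
    minimum of its cycle. A virtual pre-beat fills the run-in before the
    first annotated foot. Output is normalized to max |amp| = 1.
    """
    r_times = np.asarray(r_times, dtype=float)
    ptts = np.asarray(ptt_per_beat, dtype=float)
    _validate_ptts(r_times, ptts)
    n = _n_samples(cfg)
    x = np.zeros(n)
    if r_times.size == 0:
        return TimeSeries(x, cfg.fs)
    onsets = r_times + ptts
    seg_lengths = _segment_lengths(onsets)
    amps = _beat_amplitudes(onsets, cfg)
    t = np.arange(n) / cfg.fs

    segments = list(zip(onsets, seg_lengths, amps))
    # Virtual run-in pulse so the region before the first foot decays into it.
    med_L = float(np.median(seg_lengths))
    segments.insert(0, (onsets[0] - med_L, med_L, amps[0]))

    for o, L, a in segments:
        tau, val = _pulse_knots(L, cfg)
        spline = PchipInterpolator(tau, a * val)
        lo = max(0, int(math.ceil(o * cfg.fs)))
        hi = min(n, int(math.ceil((o + L) * cfg.fs)))
        if lo < hi:
            x[lo:hi] = spline(t[lo:hi] - o)
    peak = np.max(np.abs(x))
    if peak > 0:
        x /= peak
    return TimeSeries(x, cfg.fs)


def add_noise(ts: TimeSeries, cfg: SimConfig, stream: int = 2) -> TimeSeries:
    """Baseline wander + white Gaussian noise + Poisson-placed artifacts.

    ``stream`` decorrelates the ECG and PPG noise draws for one seed. With
    all three magnitudes zero the input is returned bit-identical.
    """
    if (
        cfg.noise_baseline_amp == 0
        and cfg.noise_gauss_sd == 0
        and cfg.artifact_rate == 0
    ):
        return ts.copy()
    rng = _rng_for(cfg, stream)
    x = ts.samples.copy()
    t = ts.times()
    if cfg.noise_baseline_amp > 0:
        f = rng.uniform(0.2, 0.4)
        phase = rng.uniform(0, 2 * np.pi)
        x += cfg.noise_baseline_amp * np.sin(2 * np.pi * f * t + phase)
    if cfg.noise_gauss_sd > 0:
        x += rng.normal(0.0, cfg.noise_gauss_sd, size=x.size)
    if cfg.artifact_rate > 0:
        n_ev = rng.poisson(cfg.artifact_rate * ts.duration / 60.0)
        sd = float(np.std(ts.samples))
        for _ in range(n_ev):
            c = rng.uniform(0, ts.duration)
            dur = rng.uniform(0.1, 0.3)
            amp = rng.uniform(2.0, 4.0) * sd * rng.choice([-1.0, 1.0])
            lo = max(0, int((c - dur / 2) * ts.fs))
            hi = min(x.size, int((c + dur / 2) * ts.fs))
            if lo < hi:
                tt = np.arange(lo, hi) / ts.fs
                x[lo:hi] += amp * np.sin(np.pi * (tt - (c - dur / 2)) / dur)
    return TimeSeries(x, ts.fs, ts.t0)


# Generative BP model: BP = c0 + c1/PTT + c2*RR + c3*PIR + c4*age + noise.
# Coefficients chosen to put SBP near 120 and DBP near 75 mmHg at the default
# operating point (PTT 0.20 s, RR 0.80 s, PIR 1.5, age 30) with a PTT
# sensitivity of about 2 mmHg per 10 ms, in line with PTT-BP regressions.
SBP_COEFFS = (71.0, 8.0, -10.0, 4.0, 0.30)
DBP_COEFFS = (49.0, 4.0, -5.0, 2.0, 0.20)


def _bp_mean(coeffs, ptt, rr, pir, age):
    c0, c1, c2, c3, c4 = coeffs
    return c0 + c1 / ptt + c2 * rr + c3 * pir + c4 * age


def generate_bp_truth(
    features_truth,
    subject_meta: dict,
    sbp_coeffs=SBP_COEFFS,
    dbp_coeffs=DBP_COEFFS,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> list[tuple[float, float, float]]:
    """Reference BP readings from the generative feature-BP relationship.

    ``features_truth`` is an iterable of (time_s, ptt, rr, pir, ...) rows
    (for this simulator: window means of the ground-truth beat features;
    trailing entries beyond PIR are ignored by the generative model).
    Gaussian reading noise is redrawn for any sample where it would invert
    the SBP > DBP ordering.
    """
    age = float(subject_meta["age"])
    rng = np.random.default_rng(seed)
    out: list[tuple[float, float, float]] = []
    for t, ptt, rr, pir, *_ in features_truth:
        ms = _bp_mean(sbp_coeffs, ptt, rr, pir, age)
        md = _bp_mean(dbp_coeffs, ptt, rr, pir, age)
        if ms <= md:
            raise ConfigurationError(
                f"coefficients give noise-free SBP {ms:.1f} <= DBP {md:.1f}"
            )
        if noise_sd == 0:
            out.append((t, ms, md))
            continue
        for _ in range(100):
            s = ms + rng.normal(0, noise_sd)
            d = md + rng.normal(0, noise_sd)
            if s > d:
                break
        else:  # pragma: no cover - essentially unreachable with sane coeffs
            s, d = ms, md
        out.append((t, s, d))
    return out


def truth_window_features(
    annotations: list[BeatAnnotation],
    cfg: SimConfig,
    window_s: float = 10.0,
    step_s: float = 5.0,
) -> list[tuple[float, float, float, float, float]]:
    """Ground-truth (time, ptt, rr, pir, t_sys) per trailing window.

    The truth PIR uses the optical-intensity convention: the pulse rides on a
    DC perfusion baseline, so PIR = (dc + amp) / dc with the per-beat pulse
    amplitude from the morphology model.
    """
    if len(annotations) < 2:
        return []
    r = np.array([a.r_time for a in annotations])
    onsets = np.array([a.onset_time for a in annotations])
    pk = np.array([a.peak_time for a in annotations])
    rr = np.diff(r)
    ptt = onsets[:-1] - r[:-1]
    tsys = pk[:-1] - onsets[:-1]
    amps = _beat_amplitudes(onsets[:-1], cfg)
    pir = (_PPG_DC + amps) / _PPG_DC
    rows = []
    t_end = r[-1]
    t = window_s
    while t <= t_end + 1e-9:
        m = (r[:-1] > t - window_s) & (r[:-1] <= t)
        if m.sum() >= 3:
            rows.append(
                (t, float(ptt[m].mean()), float(rr[m].mean()),
                 float(pir[m].mean()), float(tsys[m].mean()))
            )
        t += step_s
    return rows


def generate_subject(
    cfg: SimConfig,
    subject_id: str = "S00",
    sex: str = "M",
    age: float = 30.0,
    weight: float = 70.0,
    bp_noise_sd: float = 3.0,
    window_s: float = 10.0,
    step_s: float = 5.0,
) -> SubjectRecord:
    """One complete simulated subject: signals, truth, and reference BP."""
    r_times = generate_beat_train(cfg)
    ptts = _draw_ptts(r_times, cfg)
    ecg = add_noise(synthesize_ecg(r_times, cfg), cfg, stream=2)
    ppg = add_noise(synthesize_ppg(r_times, ptts, cfg), cfg, stream=3)
    ann = beat_annotations(r_times, ptts, cfg)
    meta = {"age": age, "weight": weight, "sex": sex}
    feats = truth_window_features(ann, cfg, window_s=window_s, step_s=step_s)
    bp_ref = generate_bp_truth(
        feats, meta, noise_sd=bp_noise_sd, seed=cfg.seed + 40000
    )
    return SubjectRecord(
        subject_id=subject_id,
        sex=sex,
        age=age,
        weight=weight,
        ecg=ecg,
        ppg=ppg,
        truth=ann,
        bp_ref=bp_ref,
        truth_features=feats,
    )


def generate_cohort(
    n_subjects: int,
    cfg: SimConfig | None = None,
    seed: int = 0,
    bp_noise_sd: float = 3.0,
    preset: str = "default",
) -> list[SubjectRecord]:
    """Cohort with per-subject physiology drawn around population norms.

    Each subject gets their own heart rate, mean PTT (the between-subject
    spread that makes the PTT-stratified split meaningful), demographics,
    and seed. With the ``default`` preset, pulse morphology is also drawn
    per subject (rise time, notch depth, dicrotic prominence, respiratory
    modulation) - a cohort of identical waveforms would misrepresent the
    inter-individual pulse variety that fiducial detectors must cope with.
    A named non-default preset pins the morphology for every subject.
    """
    if preset not in MORPHOLOGY_PRESETS:
        raise ConfigurationError(f"unknown morphology preset {preset!r}")
    base = (cfg.model_dump() if cfg is not None else SimConfig().model_dump())
    base.update(MORPHOLOGY_PRESETS[preset])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    cohort = []
    for i in range(n_subjects):
        sub = dict(base)
        sub["hr_mean"] = float(np.clip(rng.normal(75, 8), 55, 100))
        sub["ptt_mean"] = float(np.clip(rng.normal(0.20, 0.03), 0.15, 0.30))
        if preset == "default":
            sub["t_sys"] = float(rng.uniform(0.10, 0.22))
            sub["notch_depth"] = float(rng.uniform(0.35, 0.60))
            sub["dicrotic_prominence"] = float(rng.uniform(0.02, 0.28))
            sub["amp_mod_depth"] = float(rng.uniform(0.10, 0.45))
            sub["amp_mod_period_s"] = float(rng.uniform(3.5, 6.0))
        sub["seed"] = seed * 10000 + i
        sc = SimConfig(**sub)
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(np.clip(rng.normal(29.5, 9.4), 18, 65))
        weight = float(np.clip(rng.normal(70, 12), 45, 110))
        cohort.append(
            generate_subject(
                sc,
                subject_id=f"S{i:02d}",
                sex=sex,
                age=age,
                weight=weight,
                bp_noise_sd=bp_noise_sd,
            )
        )
    return cohort
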