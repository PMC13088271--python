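"""Evaluation machinery: fiducial F1, PTT error and detection rate, BP
agreement metrics (mean error, STD, RMSE, R^2, Bland-Altman limits of
agreement, the AAMI pass criterion), and the nonparametric method-comparison
battery (Kruskal-Wallis with Mann-Whitney post hocs, Wilcoxon signed-rank,
Shapiro-Wilk and Levene diagnostics, Bonferroni correction).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .baselines import pair_ptt
from .core import BeatAnnotation, FiducialSet, RPeakList

__all__ = [
    "MatchResult",
    "match_events",
    "match_and_f1",
    "fiducial_f1",
    "ptt_errors",
    "ptt_against_truth",
    "bp_agreement",
    "method_comparison",
    "BPAgreement",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def match_events(
    detected: np.ndarray, truth: np.ndarray, tol_s: float
) -> list[tuple[int, int]]:
    """Maximum-cardinality one-to-one matching within +/-tol_s.

    Both sides sorted, each truth event takes the earliest unclaimed
    detection inside its tolerance window - optimal for interval-structured
    bipartite graphs (each truth's admissible detections form a contiguous
    run), which is what time-tolerance matching produces.
    """
    det = np.sort(np.asarray(detected, dtype=float))
    tru = np.sort(np.asarray(truth, dtype=float))
    pairs: list[tuple[int, int]] = []
    j = 0
    for i, t in enumerate(tru):
        while j < det.size and det[j] < t - tol_s:
            j += 1
        if j < det.size and det[j] <= t + tol_s:
            pairs.append((j, i))
            j += 1
    return pairs


def match_and_f1(detected: np.ndarray, truth: np.ndarray, tol_s: float) -> MatchResult:
    """Precision/recall/F1 of detected event times against ground truth."""
    if tol_s <= 0:
        raise ValueError("matching tolerance must be positive")
    det = np.asarray(detected, dtype=float)
    tru = np.asarray(truth, dtype=float)
    tp = len(match_events(det, tru, tol_s))
    fp = det.size - tp
    fn = tru.size - tp
    precision = tp / det.size if det.size else 0.0
    recall = tp / tru.size if tru.size else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MatchResult(tp, fp, fn, precision, recall, f1)


def fiducial_f1(
    fid: FiducialSet, truth: list[BeatAnnotation], tol_s: float = 0.04
) -> dict[str, MatchResult]:
    """F1 per landmark type plus the pooled aggregation.

    Onsets match only truth onsets and peaks only truth peaks; "pooled"
    sums the tp/fp/fn counts over both landmark types before forming
    precision, recall and F1.
    """
    truth_on = np.array([a.onset_time for a in truth])
    truth_pk = np.array([a.peak_time for a in truth])
    res_on = match_and_f1(fid.detected_onsets(), truth_on, tol_s)
    res_pk = match_and_f1(fid.detected_peaks(), truth_pk, tol_s)
    tp = res_on.tp + res_pk.tp
    fp = res_on.fp + res_pk.fp
    fn = res_on.fn + res_pk.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "onset": res_on,
        "peak": res_pk,
        "pooled": MatchResult(tp, fp, fn, precision, recall, f1),
    }


def ptt_errors(
    est_ptt: np.ndarray, truth_ptt: np.ndarray, paired: np.ndarray
) -> tuple[float, float]:
    """(MAE in ms over paired beats, detection rate).

    With zero paired beats the MAE is undefined and returned as NaN.
    """
    est = np.asarray(est_ptt, dtype=float)
    tru = np.asarray(truth_ptt, dtype=float)
    m = np.asarray(paired, dtype=bool)
    rate = float(m.mean()) if m.size else 0.0
    if not m.any():
        return float("nan"), rate
    mae_ms = float(np.mean(np.abs(est[m] - tru[m])) * 1000.0)
    return mae_ms, rate


def ptt_against_truth(
    truth: list[BeatAnnotation],
    fid: FiducialSet,
    fs: float,
    max_lag_frac: float = 0.9,
) -> tuple[float, float, np.ndarray]:
    """Beat-wise PTT error of a method versus simulator ground truth.

    Ground-truth R waves anchor the pairing; eligible beats are those
    forming a complete cardiac cycle (a successor R exists, since R-to-onset
    pairing is defined per RR interval). Returns (MAE ms, detection rate,
    signed per-beat errors in ms for the paired beats).
    """
    if len(truth) < 2:
        return float("nan"), 0.0, np.empty(0)
    r_times = np.array([a.r_time for a in truth])
    true_ptt = np.array([a.ptt for a in truth])
    r_idx = np.round(r_times * fs).astype(int)
    rpl = RPeakList(r_idx, fs)
    ptt, paired, _ = pair_ptt(rpl, fid, max_lag_frac=max_lag_frac)
    # Complete cycles only: drop the final beat, which has no RR interval.
    ptt, paired, true_ptt = ptt[:-1], paired[:-1], true_ptt[:-1]
    mae, rate = ptt_errors(ptt, true_ptt, paired)
    errs_ms = (ptt[paired] - true_ptt[paired]) * 1000.0
    return mae, rate, errs_ms


@dataclass
class BPAgreement:
    """Device-minus-reference agreement summary for one BP quantity."""

    n: int
    me: float  # mean error, mmHg
    std: float  # sample SD of errors, mmHg
    mae: float
    rmse: float
    r2: float
    loa_low: float  # me - 1.96 * std
    loa_high: float  # me + 1.96 * std
    pct_within_loa: float  # percent of differences inside the LoA
    aami_pass: bool  # |me| <= 5 and std <= 8, exactly

    def as_dict(self) -> dict:
        return asdict(self)


def bp_agreement(pred: np.ndarray, ref: np.ndarray) -> BPAgreement:
    """Bland-Altman style agreement between predicted and reference BP."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.size != ref.size:
        raise ValueError("pred and ref must be the same length")
    if pred.size < 3:
        raise ValueError("agreement metrics need at least 3 pairs")
    d = pred - ref
    me = float(np.mean(d))
    std = float(np.std(d, ddof=1))
    mae = float(np.mean(np.abs(d)))
    rmse = float(np.sqrt(np.mean(d**2)))
    sstot = float(np.sum((ref - ref.mean()) ** 2))
    r2 = float(1.0 - np.sum(d**2) / sstot) if sstot > 0 else float("nan")
    loa_low, loa_high = me - 1.96 * std, me + 1.96 * std
    inside = (d >= loa_low) & (d <= loa_high)
    return BPAgreement(
        n=int(pred.size),
        me=me,
        std=std,
        mae=mae,
        rmse=rmse,
        r2=r2,
        loa_low=loa_low,
        loa_high=loa_high,
        pct_within_loa=float(100.0 * inside.mean()),
        aami_pass=bool(abs(me) <= 5.0 and std <= 8.0),
    )


def method_comparison(
    errors_by_method: dict[str, np.ndarray],
    paired: bool = False,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Nonparametric test battery over per-beat (or per-sample) errors.

    Unpaired mode: Kruskal-Wallis across all groups, then pairwise
    Mann-Whitney U post hocs with Bonferroni correction. Paired mode (two
    groups of equal length): Wilcoxon signed-rank. Shapiro-Wilk and Levene
    diagnostics are reported alongside. All tests two-sided; groups with
    fewer than 3 values are skipped with a log message.
    """
    groups = {
        k: np.asarray(v, dtype=float) for k, v in errors_by_method.items()
    }
    usable = {k: v for k, v in groups.items() if v.size >= 3}
    for k in groups.keys() - usable.keys():
        log.warning("group %r has < 3 values; skipped from comparison", k)
    out: dict[str, dict] = {}
    if len(usable) < 2:
        return out

    def entry(stat, p, n_comp=1):
        corrected = min(1.0, p * n_comp)
        return {
            "statistic": float(stat),
            "p": float(p),
            "corrected_p": float(corrected),
            "significant": bool(corrected < alpha),
        }

    for k, v in usable.items():
        sub = v if v.size <= 5000 else v[:5000]  # Shapiro's validity range
        w, p = stats.shapiro(sub)
        out[f"shapiro[{k}]"] = entry(w, p)
    lv_stat, lv_p = stats.levene(*usable.values())
    out["levene"] = entry(lv_stat, lv_p)

    if paired:
        if len(usable) != 2:
            raise ValueError("paired mode requires exactly 2 groups")
        (ka, va), (kb, vb) = usable.items()
        if va.size != vb.size:
            raise ValueError("paired mode requires equal-length groups")
        w, p = stats.wilcoxon(va, vb)
        out[f"wilcoxon[{ka} vs {kb}]"] = entry(w, p)
        return out

    h, p = stats.kruskal(*usable.values())
    out["kruskal"] = entry(h, p)
    pairs = list(itertools.combinations(usable, 2))
    for ka, kb in pairs:
        u, up = stats.mannwhitneyu(usable[ka], usable[kb], alternative="two-sided")
        out[f"mannwhitney[{ka} vs {kb}]"] = entry(u, up, n_comp=len(pairs))
    return out
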