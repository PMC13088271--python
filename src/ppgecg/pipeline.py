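"""End-to-end orchestration: simulate -> preprocess -> R-detect -> couple ->
detect fiducials -> features -> train -> predict -> evaluate.

Each stage's output is written as plain text under the artifact directory,
with a manifest recording the exact configuration, its hash, and the seed, so
a rerun with the same config is bit-identical in provenance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .baselines import (
    DerivativeParams,
    LocalExtremaParams,
    detect_derivative,
    detect_local_extrema,
)
from .config import RunConfig
from .core import FiducialSet, PpgEcgError, SubjectRecord, TimeSeries
from .couple import CoupleParams, compute_beat_features, couple_signals, detect_fiducials_coupled
from .evalstats import bp_agreement, fiducial_f1, method_comparison, ptt_against_truth
from .features_bp import (
    FEATURE_SCHEMA,
    predict_bp,
    sliding_features,
    split_by_ptt_strata,
    tukey_filter,
    tune_and_train,
)
from .preprocess import bandpass_zero_phase, scale_for_coupling
from .rdetect import RDetectParams, detect_r_peaks, sparsify_ecg
from .siggen import generate_cohort

__all__ = [
    "SubjectResult",
    "process_subject",
    "build_feature_table",
    "run_bp_experiment",
    "evaluate_methods",
    "run_pipeline",
    "ARTIFACT_KINDS",
]

log = logging.getLogger(__name__)

#: The artifact kinds a full pipeline run writes, in stage order.
ARTIFACT_KINDS = [
    "signals",
    "annotations",
    "filtered",
    "rpeaks",
    "coupled",
    "fiducials",
    "features",
    "model",
    "eval",
]


def _rdetect_params(cfg: RunConfig) -> RDetectParams:
    r = cfg.rdetect
    return RDetectParams(
        c=r.c,
        lam=r.lam,
        refractory_s=r.refractory_s,
        refine_halfwidth_s=r.refine_halfwidth_s,
        warmup_s=r.warmup_s,
    )


def _couple_params(cfg: RunConfig) -> CoupleParams:
    c = cfg.couple
    return CoupleParams(
        alpha=c.alpha, beta=c.beta, window_lo=c.window_lo, window_hi=c.window_hi
    )


@dataclass
class SubjectResult:
    """Per-subject intermediates from one pipeline pass."""

    record: SubjectRecord
    ecg_filt: TimeSeries
    ppg_filt: TimeSeries
    peaks: object
    coupled: TimeSeries
    fid_coupled: FiducialSet
    fid_local: FiducialSet
    fid_deriv: FiducialSet
    beats: list
    n_skipped: int


def process_subject(
    rec: SubjectRecord, cfg: RunConfig, filtered: bool = True
) -> SubjectResult:
    """Run preprocessing, coupling and all three detectors on one subject.

    ``filtered=False`` bypasses the bandpass (for zero-noise oracle runs,
    where there is no drift or noise to remove and filtering would itself
    reshape the waveform by a few samples).
    """
    if filtered:
        ecg_f = bandpass_zero_phase(rec.ecg, cfg.filter.low_hz, cfg.filter.high_hz)
        ppg_f = bandpass_zero_phase(rec.ppg, cfg.filter.low_hz, cfg.filter.high_hz)
    else:
        ecg_f, ppg_f = rec.ecg.copy(), rec.ppg.copy()
    peaks = detect_r_peaks(ecg_f, _rdetect_params(cfg))
    ppg_s = scale_for_coupling(ppg_f, ecg_f, cfg.couple.amp_ratio)
    ecg_sp = sparsify_ecg(ecg_f, peaks, cfg.rdetect.keep_halfwidth_s)
    cp = _couple_params(cfg)
    coupled = couple_signals(ppg_s, ecg_sp, cp)
    fid = detect_fiducials_coupled(coupled, peaks, cp)
    beats, skipped = compute_beat_features(
        fid, coupled, cp, ecg_sparse=ecg_sp, pir_mode="baseline_restored"
    )
    b = cfg.baseline
    fid_local = detect_local_extrema(
        ppg_f,
        LocalExtremaParams(
            min_peak_dist_s=b.min_peak_dist_s,
            amp_frac=b.amp_frac,
            roll_n=b.roll_n,
            lookback_s=b.lookback_s,
        ),
    )
    fid_deriv = detect_derivative(
        ppg_f,
        DerivativeParams(
            deriv_frac=b.deriv_frac,
            roll_window_s=b.deriv_window_s,
            refractory_s=b.refractory_s,
            onset_mode=b.onset_mode,
        ),
    )
    return SubjectResult(
        record=rec,
        ecg_filt=ecg_f,
        ppg_filt=ppg_f,
        peaks=peaks,
        coupled=coupled,
        fid_coupled=fid,
        fid_local=fid_local,
        fid_deriv=fid_deriv,
        beats=beats,
        n_skipped=skipped,
    )


def build_feature_table(results: list[SubjectResult], cfg: RunConfig) -> pd.DataFrame:
    """Windowed feature rows joined with reference BP, Tukey-screened.

    One row per (subject, emission time); reference readings land on the
    same emission grid, so the join is exact. Per-subject Tukey fences on
    SBP and DBP drop outlier readings.
    """
    frames = []
    for res in results:
        rec = res.record
        feats = sliding_features(res.beats, cfg.model.window_s, cfg.model.step_s)
        if feats.empty:
            log.warning("subject %s produced no feature windows", rec.subject_id)
            continue
        bp = pd.DataFrame(rec.bp_ref, columns=["window_time", "sbp", "dbp"])
        feats["key"] = feats["window_time"].round(6)
        bp["key"] = bp["window_time"].round(6)
        df = feats.merge(bp.drop(columns="window_time"), on="key").drop(columns="key")
        if df.empty:
            continue
        df["subject_id"] = rec.subject_id
        df["sex"] = 1.0 if rec.sex == "M" else 0.0
        df["age"] = rec.age
        df["weight"] = rec.weight
        if len(df) >= 4:
            _, ms = tukey_filter(df["sbp"].to_numpy(), cfg.model.tukey_k)
            _, md = tukey_filter(df["dbp"].to_numpy(), cfg.model.tukey_k)
            df = df[ms & md]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=FEATURE_SCHEMA + ["subject_id", "window_time", "sbp", "dbp"])
    return pd.concat(frames, ignore_index=True)


def run_bp_experiment(
    results: list[SubjectResult], cfg: RunConfig
) -> dict:
    """PTT-stratified split, TPE-tuned SBP/DBP models, held-out agreement."""
    table = build_feature_table(results, cfg)
    if table.empty:
        raise PpgEcgError("no feature rows available for BP modelling")
    mean_ptt = table.groupby("subject_id")["ptt_avg"].mean().to_dict()
    if len(mean_ptt) >= 5:
        train_ids, test_ids = split_by_ptt_strata(
            mean_ptt, test_frac=cfg.model.test_frac, seed=cfg.seed
        )
    else:
        ids = sorted(mean_ptt)
        n_test = max(1, int(round(len(ids) * cfg.model.test_frac)))
        train_ids, test_ids = ids[:-n_test], ids[-n_test:]
        log.warning(
            "fewer than 5 subjects: falling back to a deterministic %d/%d split",
            len(train_ids),
            len(test_ids),
        )
    train = table[table.subject_id.isin(train_ids)]
    test = table[table.subject_id.isin(test_ids)]
    bundle = tune_and_train(
        train,
        budget=cfg.model.trials,
        seed=cfg.seed,
        cv_folds=cfg.model.cv_folds,
    )
    preds = predict_bp(bundle, test)
    ref_mbp = test["dbp"] + (test["sbp"] - test["dbp"]) / 3.0
    agreement = {
        "sbp": bp_agreement(preds["sbp"].to_numpy(), test["sbp"].to_numpy()),
        "dbp": bp_agreement(preds["dbp"].to_numpy(), test["dbp"].to_numpy()),
        "mbp": bp_agreement(preds["mbp"].to_numpy(), ref_mbp.to_numpy()),
    }
    return {
        "table": table,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "bundle": bundle,
        "test": test,
        "preds": preds,
        "agreement": agreement,
    }


def evaluate_methods(results: list[SubjectResult], cfg: RunConfig) -> dict:
    """Cohort-level F1, PTT MAE/detection rate, and the test battery.

    F1 counts are pooled across subjects per method; PTT errors are
    concatenated across subjects; the Kruskal-Wallis + Mann-Whitney battery
    runs on the absolute per-beat PTT errors of the three methods.
    """
    methods = {
        "coupled": lambda r: r.fid_coupled,
        "local_extrema": lambda r: r.fid_local,
        "derivative": lambda r: r.fid_deriv,
    }
    out: dict = {"per_method": {}}
    errors_by_method: dict[str, np.ndarray] = {}
    for name, get in methods.items():
        tp = fp = fn = 0
        errs = []
        paired = total = 0
        for res in results:
            fid = get(res)
            f1s = fiducial_f1(fid, res.record.truth, cfg.eval.tol_s)
            tp += f1s["pooled"].tp
            fp += f1s["pooled"].fp
            fn += f1s["pooled"].fn
            _, _, e = ptt_against_truth(res.record.truth, fid, res.record.ecg.fs)
            errs.append(e)
            n_elig = max(0, len(res.record.truth) - 1)
            total += n_elig
            paired += e.size
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        errs = np.concatenate(errs) if errs else np.empty(0)
        errors_by_method[name] = np.abs(errs)
        out["per_method"][name] = {
            "f1": f1,
            "precision": precision,
            "recall": recall,
            "ptt_mae_ms": float(np.mean(np.abs(errs))) if errs.size else float("nan"),
            "ptt_detection_rate": paired / total if total else 0.0,
            "n_beats": total,
        }
    out["tests"] = method_comparison(errors_by_method, paired=False, alpha=cfg.eval.alpha)
    return out


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PpgEcgError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapper
        raise PpgEcgError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Execute every stage and write the nine artifact kinds plus manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    cohort = _stage(
        "simulate",
        generate_cohort,
        cfg.cohort.n_subjects,
        cfg=cfg.sim,
        seed=cfg.seed,
        bp_noise_sd=cfg.model.bp_noise_sd,
        preset=cfg.cohort.preset,
    )
    (out / "signals").mkdir(exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    for rec in cohort:
        pio.write_signal(out / "signals" / f"{rec.subject_id}_ecg.txt", rec.ecg)
        pio.write_signal(out / "signals" / f"{rec.subject_id}_ppg.txt", rec.ppg)
        pio.write_annotations(out / "annotations" / f"{rec.subject_id}.json", rec.truth)
        pio.write_json(
            out / "annotations" / f"{rec.subject_id}_meta.json",
            {
                "subject_id": rec.subject_id,
                "sex": rec.sex,
                "age": rec.age,
                "weight": rec.weight,
                "bp_ref": rec.bp_ref,
            },
        )

    results = [
        _stage(f"process[{rec.subject_id}]", process_subject, rec, cfg)
        for rec in cohort
    ]
    for sub in ("filtered", "rpeaks", "coupled", "fiducials"):
        (out / sub).mkdir(exist_ok=True)
    for res in results:
        sid = res.record.subject_id
        pio.write_signal(out / "filtered" / f"{sid}_ecg.txt", res.ecg_filt)
        pio.write_signal(out / "filtered" / f"{sid}_ppg.txt", res.ppg_filt)
        pio.write_json(out / "rpeaks" / f"{sid}.json", {"r_times": res.peaks.r_times})
        pio.write_signal(out / "coupled" / f"{sid}.txt", res.coupled)
        for fid, tag in (
            (res.fid_coupled, "coupled"),
            (res.fid_local, "local_extrema"),
            (res.fid_deriv, "derivative"),
        ):
            pio.write_json(
                out / "fiducials" / f"{sid}_{tag}.json",
                {
                    "onset_times": fid.onset_times,
                    "peak_times": fid.peak_times,
                    "source_method": fid.source_method,
                },
            )

    bp = _stage("train", run_bp_experiment, results, cfg)
    bp["table"].to_csv(out / "features.csv", index=False)
    model_dir = out / "model"
    model_dir.mkdir(exist_ok=True)
    bp["bundle"].sbp_model.get_booster().save_model(model_dir / "sbp.json")
    bp["bundle"].dbp_model.get_booster().save_model(model_dir / "dbp.json")
    pio.write_json(model_dir / "schema.json", bp["bundle"].feature_schema)
    pio.write_json(
        model_dir / "manifest.json",
        {
            "hyperparams": bp["bundle"].hyperparams,
            "train_manifest": bp["bundle"].train_manifest,
            "train_ids": bp["train_ids"],
            "test_ids": bp["test_ids"],
        },
    )

    ev = _stage("evaluate", evaluate_methods, results, cfg)
    (out / "eval").mkdir(exist_ok=True)
    report = {
        "methods": ev["per_method"],
        "tests": ev["tests"],
        "bp_agreement": {k: v.as_dict() for k, v in bp["agreement"].items()},
    }
    pio.write_json(out / "eval" / "report.json", report)

    manifest = {
        "config": cfg.model_dump(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "artifacts": ARTIFACT_KINDS,
    }
    pio.write_json(out / "manifest.json", manifest)
    pio.write_sidecar(out / "eval" / "report.json", cfg)
    return out
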