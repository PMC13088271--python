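"""Feature conditioning and the multi-feature SBP/DBP estimation models.

Beat-level features (RR, PTT, PIR, T) are averaged over a trailing sliding
window and emitted at fixed intervals; 1/PTT and ln(PTT) augment the feature
set (the standard PTT-BP linearizations); demographics are appended. Separate
gradient-boosted tree regressors for SBP and DBP are tuned by TPE over nine
hyperparameters with subject-grouped cross-validated R^2 as the objective,
after a PTT-stratified subject-wise train/test split that rules out subject
leakage by construction.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score
from sklearn.model_selection import GroupKFold
from xgboost import XGBRegressor

from .core import BeatFeatures, ConfigurationError, SchemaError
from .tpe import ParamSpec, TPEOptimizer

__all__ = [
    "FEATURE_SCHEMA",
    "sliding_features",
    "tukey_filter",
    "split_by_ptt_strata",
    "tune_and_train",
    "predict_bp",
    "ModelBundle",
]

log = logging.getLogger(__name__)

#: Ordered model inputs: waveform features, their nonlinear transforms, and
#: physical characteristics.
FEATURE_SCHEMA = [
    "rr_avg",
    "ptt_avg",
    "pir_avg",
    "t_avg",
    "inv_ptt",
    "ln_ptt",
    "sex",  # 0 = F, 1 = M
    "age",
    "weight",
]

#: TPE search space: the nine boosted-tree hyperparameters under tuning.
SEARCH_SPACE = [
    ParamSpec("n_estimators", "int", 50, 600),
    ParamSpec("learning_rate", "loguniform", 0.005, 0.3),
    ParamSpec("max_depth", "int", 2, 8),
    ParamSpec("min_child_weight", "uniform", 1.0, 10.0),
    ParamSpec("reg_alpha", "loguniform", 1e-8, 10.0),
    ParamSpec("reg_lambda", "loguniform", 1e-8, 10.0),
    ParamSpec("gamma", "uniform", 0.0, 5.0),
    ParamSpec("subsample", "uniform", 0.5, 1.0),
    ParamSpec("colsample_bytree", "uniform", 0.5, 1.0),
]


def sliding_features(
    beats: list[BeatFeatures],
    window_s: float = 10.0,
    step_s: float = 5.0,
    duration_s: float | None = None,
) -> pd.DataFrame:
    """Trailing-window means of beat features, emitted every ``step_s``.

    Windows are (t - window_s, t]; windows holding fewer than 3 beats are
    skipped. Emission starts once one full window fits and runs to
    ``duration_s`` (default: the last beat time).
    """
    cols = ["window_time", "rr_avg", "ptt_avg", "pir_avg", "t_avg", "inv_ptt", "ln_ptt"]
    if not beats:
        return pd.DataFrame(columns=cols)
    r = np.array([b.r_time for b in beats])
    rr = np.array([b.rr for b in beats])
    ptt = np.array([b.ptt for b in beats])
    pir = np.array([b.pir for b in beats])
    tsys = np.array([b.t_sys for b in beats])
    rows = []
    t = window_s
    t_end = duration_s if duration_s is not None else r.max()
    while t <= t_end + 1e-9:
        m = (r > t - window_s) & (r <= t)
        if m.sum() >= 3:
            pa = float(ptt[m].mean())
            rows.append(
                {
                    "window_time": t,
                    "rr_avg": float(rr[m].mean()),
                    "ptt_avg": pa,
                    "pir_avg": float(pir[m].mean()),
                    "t_avg": float(tsys[m].mean()),
                    "inv_ptt": 1.0 / pa,
                    "ln_ptt": float(np.log(pa)),
                }
            )
        t += step_s
    return pd.DataFrame(rows, columns=cols)


def truth_feature_table(cohort) -> pd.DataFrame:
    """Model-ready rows built from simulator ground truth (no detection).

    Bypasses the signal pipeline entirely: window features come from the
    annotated beats and targets from the generative BP model, which makes
    this the clean substrate for parameter-recovery experiments on the
    feature-to-BP mapping itself.
    """
    frames = []
    for rec in cohort:
        if not rec.truth_features:
            continue
        df = pd.DataFrame(
            rec.truth_features,
            columns=["window_time", "ptt_avg", "rr_avg", "pir_avg", "t_avg"],
        )
        df["inv_ptt"] = 1.0 / df["ptt_avg"]
        df["ln_ptt"] = np.log(df["ptt_avg"])
        bp = pd.DataFrame(rec.bp_ref, columns=["window_time", "sbp", "dbp"])
        df = df.merge(bp, on="window_time")
        df["subject_id"] = rec.subject_id
        df["sex"] = 1.0 if rec.sex == "M" else 0.0
        df["age"] = rec.age
        df["weight"] = rec.weight
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=FEATURE_SCHEMA + ["subject_id", "window_time", "sbp", "dbp"]
        )
    return pd.concat(frames, ignore_index=True)


def tukey_filter(values: np.ndarray, k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Tukey's-fence outlier screen: keep Q1 - k*IQR <= x <= Q3 + k*IQR.

    Returns (kept values, boolean keep-mask). Fewer than 4 readings are
    passed through unfiltered with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 readings: Tukey fence not applied", stacklevel=2)
        return x, np.ones(x.size, dtype=bool)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    mask = (x >= q1 - k * iqr) & (x <= q3 + k * iqr)
    return x[mask], mask


def split_by_ptt_strata(
    subject_ptt: dict[str, float], test_frac: float = 0.2, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Subject-wise split stratified by mean-PTT tertile.

    Subjects are ranked by mean PTT, cut into three tiers (short, medium,
    long), and each tier is split train/test at ``1 - test_frac`` :
    ``test_frac``; the overall test count is fixed at round(n * test_frac)
    and distributed over tiers by largest remainder. A tier with fewer than
    2 subjects is merged with its neighbour.
    """
    ids = list(subject_ptt)
    n = len(ids)
    if n < 5:
        raise ConfigurationError(f"need at least 5 subjects to stratify, got {n}")
    order = sorted(ids, key=lambda s: (subject_ptt[s], s))
    tiers = [list(t) for t in np.array_split(order, 3)]
    merged = []
    for t in tiers:
        if merged and len(t) < 2:
            log.warning("merging a %d-subject PTT tier with its neighbour", len(t))
            merged[-1].extend(t)
        else:
            merged.append(t)
    tiers = merged
    n_test_total = int(round(n * test_frac))
    quota = [len(t) * test_frac for t in tiers]
    base = [int(q) for q in quota]
    rem = n_test_total - sum(base)
    frac_order = sorted(range(len(tiers)), key=lambda i: quota[i] - base[i], reverse=True)
    for i in frac_order[:max(0, rem)]:
        base[i] += 1
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for t, n_test in zip(tiers, base):
        perm = list(rng.permutation(t))
        test.extend(perm[:n_test])
        train.extend(perm[n_test:])
    assert not set(train) & set(test), "subject leaked into both sets"
    return sorted(train), sorted(test)


@dataclass
class ModelBundle:
    """Fitted SBP and DBP regressors plus everything needed to reuse them."""

    sbp_model: XGBRegressor
    dbp_model: XGBRegressor
    feature_schema: list[str]
    hyperparams: dict[str, dict]
    train_manifest: dict = field(default_factory=dict)


def _make_model(params: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
        **params,
    )


def _cv_r2(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, params: dict, seed: int, folds: int
) -> float:
    n_groups = np.unique(groups).size
    k = min(folds, n_groups)
    if k < 2:
        raise ConfigurationError("grouped CV needs at least 2 subjects in training")
    scores = []
    for tr, va in GroupKFold(n_splits=k).split(X, y, groups):
        m = _make_model(params, seed)
        m.fit(X[tr], y[tr])
        scores.append(r2_score(y[va], m.predict(X[va])))
    return float(np.mean(scores))


def tune_and_train(
    train_rows: pd.DataFrame,
    targets: tuple[str, ...] = ("sbp", "dbp"),
    budget: int = 50,
    seed: int = 0,
    cv_folds: int = 5,
) -> ModelBundle:
    """TPE search + refit for separate SBP and DBP models.

    ``train_rows`` must carry the feature schema columns, a ``subject_id``
    column (grouping unit for CV), and the target columns. The objective is
    mean R^2 under subject-grouped K-fold CV; the best configuration is
    refit on all training rows.
    """
    if budget < 10:
        raise ConfigurationError(f"search budget must be at least 10 trials, got {budget}")
    missing = [c for c in FEATURE_SCHEMA + ["subject_id", *targets] if c not in train_rows]
    if missing:
        raise SchemaError(f"training table is missing columns: {missing}")
    X = train_rows[FEATURE_SCHEMA].to_numpy(dtype=float)
    groups = train_rows["subject_id"].to_numpy()
    models: dict[str, XGBRegressor] = {}
    hps: dict[str, dict] = {}
    for ti, target in enumerate(targets):
        y = train_rows[target].to_numpy(dtype=float)
        opt = TPEOptimizer(SEARCH_SPACE, seed=seed * 7919 + ti)
        for _ in range(budget):
            params = opt.ask()
            score = _cv_r2(X, y, groups, params, seed, cv_folds)
            opt.tell(params, -score)  # TPE minimizes
        best_params, best_loss = opt.best
        log.info("%s: best CV R^2 = %.4f with %s", target, -best_loss, best_params)
        model = _make_model(best_params, seed)
        model.fit(X, y)
        models[target] = model
        hps[target] = dict(best_params)
    return ModelBundle(
        sbp_model=models["sbp"],
        dbp_model=models["dbp"],
        feature_schema=list(FEATURE_SCHEMA),
        hyperparams=hps,
        train_manifest={
            "subjects": sorted(map(str, np.unique(groups))),
            "seed": seed,
            "budget": budget,
            "cv_folds": cv_folds,
            "n_rows": int(len(train_rows)),
        },
    )


def predict_bp(bundle: ModelBundle, rows: pd.DataFrame) -> pd.DataFrame:
    """Per-row SBP/DBP/MBP predictions in mmHg.

    MBP uses the standard clinical estimate DBP + (SBP - DBP)/3. Predictions
    are clipped to the physiological range [30, 250] mmHg, with a ``clipped``
    flag when the clip fires.
    """
    if len(rows) == 0:
        return pd.DataFrame(columns=["sbp", "dbp", "mbp", "clipped"])
    missing = [c for c in bundle.feature_schema if c not in rows]
    if missing:
        raise SchemaError(f"prediction rows are missing fields: {missing}")
    X = rows[bundle.feature_schema].to_numpy(dtype=float)
    sbp = bundle.sbp_model.predict(X).astype(float)
    dbp = bundle.dbp_model.predict(X).astype(float)
    raw = np.stack([sbp, dbp])
    clipped_vals = np.clip(raw, 30.0, 250.0)
    clipped = np.any(clipped_vals != raw, axis=0)
    sbp, dbp = clipped_vals
    mbp = dbp + (sbp - dbp) / 3.0
    return pd.DataFrame(
        {"sbp": sbp, "dbp": dbp, "mbp": mbp, "clipped": clipped},
        index=rows.index,
    )
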