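"""Sliding-window features, outlier screening, stratified splitting, and
the TPE-tuned BP models."""
import numpy as np
import pandas as pd
import pytest

from ppgecg import (
    ModelBundle,
    generate_cohort,
    predict_bp,
    sliding_features,
    split_by_ptt_strata,
    tukey_filter,
    tune_and_train,
)
from ppgecg.core import BeatFeatures, ConfigurationError, SchemaError
from ppgecg.features_bp import FEATURE_SCHEMA, truth_feature_table
from ppgecg.tpe import ParamSpec, TPEOptimizer, minimize


def _beats(times, ptt=0.2, rr=0.8, pir=1.5, t_sys=0.15):
    return [BeatFeatures(r_time=t, rr=rr, ptt=ptt, pir=pir, t_sys=t_sys) for t in times]


class TestSlidingFeatures:
    def test_constant_features_give_constant_means(self):
        rows = sliding_features(_beats(np.arange(0.5, 60, 0.8)), 10.0, 5.0)
        np.testing.assert_allclose(rows["ptt_avg"], 0.2, rtol=1e-12)
        np.testing.assert_allclose(rows["rr_avg"], 0.8, rtol=1e-12)

    def test_row_count_matches_emission_grid(self):
        # 60 s of beats, 10 s window, 5 s step: emissions at 10,15,...,60.
        rows = sliding_features(
            _beats(np.arange(0.5, 60.5, 0.8)), 10.0, 5.0, duration_s=60.0
        )
        assert len(rows) == (60 - 10) // 5 + 1

    def test_nonlinear_transforms_exact(self):
        rows = sliding_features(_beats(np.arange(0.5, 30, 0.8)), 10.0, 5.0)
        assert rows["inv_ptt"].iloc[0] == pytest.approx(5.0)
        assert rows["ln_ptt"].iloc[0] == pytest.approx(np.log(0.2))

    def test_sparse_windows_skipped(self):
        rows = sliding_features(_beats([1.0, 30.0, 30.5, 31.0, 31.5]), 10.0, 5.0)
        assert (rows["window_time"] >= 35.0).all()


class TestTukeyFilter:
    def test_worked_fence_example(self):
        # Q1=100, Q3=120 -> fences [70, 150].
        vals = np.array([100, 100, 100, 105, 110, 115, 120, 120, 120, 149, 151, 69])
        kept, mask = tukey_filter(vals, 1.5)
        assert 149 in kept and 151 not in kept and 69 not in kept

    def test_identical_values_all_kept(self):
        kept, mask = tukey_filter(np.full(10, 100.0))
        assert mask.all()

    def test_single_gross_outlier_removed(self):
        vals = np.array([100.0] * 9 + [300.0])
        kept, mask = tukey_filter(vals)
        assert kept.size == 9 and not mask[-1]

    def test_few_readings_passed_through_with_warning(self):
        with pytest.warns(UserWarning):
            kept, mask = tukey_filter(np.array([1.0, 2.0, 3.0]))
        assert mask.all()


class TestSplit:
    def _ptts(self, n):
        rng = np.random.default_rng(0)
        return {f"S{i:02d}": float(p) for i, p in enumerate(rng.uniform(0.15, 0.3, n))}

    def test_fifteen_subjects_give_12_3_with_one_test_per_tier(self):
        ptts = self._ptts(15)
        train, test = split_by_ptt_strata(ptts, 0.2, seed=1)
        assert len(train) == 12 and len(test) == 3
        tiers = np.array_split(sorted(ptts, key=ptts.get), 3)
        for tier in tiers:
            assert sum(s in test for s in tier) == 1

    def test_twenty_four_subjects_give_19_5(self):
        train, test = split_by_ptt_strata(self._ptts(24), 0.2, seed=3)
        assert len(train) == 19 and len(test) == 5

    def test_disjoint_and_deterministic(self):
        ptts = self._ptts(11)
        a = split_by_ptt_strata(ptts, 0.2, seed=9)
        b = split_by_ptt_strata(ptts, 0.2, seed=9)
        assert a == b
        assert not set(a[0]) & set(a[1])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            split_by_ptt_strata(self._ptts(4))


@pytest.fixture(scope="module")
def recovery_setup():
    """Noise-free generative cohort split subject-wise: the BP mapping is
    exactly learnable, so this isolates model-fitting quality."""
    cohort = generate_cohort(24, seed=2, bp_noise_sd=0.0)
    table = truth_feature_table(cohort)
    mean_ptt = table.groupby("subject_id")["ptt_avg"].mean().to_dict()
    train_ids, test_ids = split_by_ptt_strata(mean_ptt, 0.2, seed=2)
    return table, train_ids, test_ids


@pytest.fixture(scope="module")
def recovery_bundle(recovery_setup):
    table, train_ids, _ = recovery_setup
    return tune_and_train(table[table.subject_id.isin(train_ids)], budget=12, seed=2)


class TestTuneAndTrain:
    def test_parameter_recovery_on_held_out_subjects(self, recovery_setup, recovery_bundle):
        from sklearn.metrics import r2_score

        table, _, test_ids = recovery_setup
        test = table[table.subject_id.isin(test_ids)]
        preds = predict_bp(recovery_bundle, test)
        assert r2_score(test["sbp"], preds["sbp"]) >= 0.9
        assert r2_score(test["dbp"], preds["dbp"]) >= 0.9
        me = float(np.mean(preds["sbp"].to_numpy() - test["sbp"].to_numpy()))
        assert abs(me) <= 2.0

    def test_shuffled_targets_fail_as_negative_control(self, recovery_setup):
        from sklearn.metrics import r2_score

        table, train_ids, test_ids = recovery_setup
        rng = np.random.default_rng(4)
        shuffled = table.copy()
        shuffled["sbp"] = rng.permutation(shuffled["sbp"].to_numpy())
        shuffled["dbp"] = rng.permutation(shuffled["dbp"].to_numpy())
        bundle = tune_and_train(
            shuffled[shuffled.subject_id.isin(train_ids)], budget=10, seed=4
        )
        test = shuffled[shuffled.subject_id.isin(test_ids)]
        preds = predict_bp(bundle, test)
        assert r2_score(test["sbp"], preds["sbp"]) <= 0.1

    def test_same_seed_selects_identical_hyperparameters(self, recovery_setup):
        table, train_ids, _ = recovery_setup
        train = table[table.subject_id.isin(train_ids)]
        a = tune_and_train(train, budget=10, seed=6)
        b = tune_and_train(train, budget=10, seed=6)
        assert a.hyperparams == b.hyperparams

    def test_undersized_budget_rejected(self, recovery_setup):
        table, train_ids, _ = recovery_setup
        with pytest.raises(ConfigurationError):
            tune_and_train(table[table.subject_id.isin(train_ids)], budget=5)


class TestPredict:
    def test_mbp_formula(self, recovery_setup, recovery_bundle):
        table, _, test_ids = recovery_setup
        test = table[table.subject_id.isin(test_ids)].head(5)
        preds = predict_bp(recovery_bundle, test)
        expect = preds["dbp"] + (preds["sbp"] - preds["dbp"]) / 3.0
        np.testing.assert_allclose(preds["mbp"], expect, rtol=1e-12)

    def test_empty_rows_give_empty_output(self, recovery_bundle):
        out = predict_bp(recovery_bundle, pd.DataFrame(columns=FEATURE_SCHEMA))
        assert len(out) == 0

    def test_schema_mismatch_names_missing_fields(self, recovery_setup, recovery_bundle):
        table, _, test_ids = recovery_setup
        bad = table[table.subject_id.isin(test_ids)].drop(columns=["inv_ptt", "age"])
        with pytest.raises(SchemaError, match="inv_ptt"):
            predict_bp(recovery_bundle, bad)


class TestTPE:
    SPACE = [
        ParamSpec("x", "uniform", -2.0, 2.0),
        ParamSpec("k", "int", 1, 20),
        ParamSpec("lr", "loguniform", 1e-4, 1.0),
    ]

    def test_deterministic_given_seed(self):
        def obj(p):
            return (p["x"] - 0.5) ** 2 + (p["k"] - 7) ** 2 + np.log(p["lr"]) ** 2

        a = minimize(obj, self.SPACE, n_trials=30, seed=5)
        b = minimize(obj, self.SPACE, n_trials=30, seed=5)
        assert a[0] == b[0] and a[1] == b[1]

    def test_concentrates_near_optimum(self):
        def obj(p):
            return (p["x"] - 0.5) ** 2

        best, loss, _ = minimize(obj, self.SPACE[:1], n_trials=60, seed=1)
        assert abs(best["x"] - 0.5) < 0.2

    def test_bounds_respected(self):
        opt = TPEOptimizer(self.SPACE, seed=3)
        for _ in range(40):
            p = opt.ask()
            assert -2.0 <= p["x"] <= 2.0
            assert 1 <= p["k"] <= 20 and isinstance(p["k"], int)
            assert 1e-4 <= p["lr"] <= 1.0
            opt.tell(p, p["x"] ** 2)
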