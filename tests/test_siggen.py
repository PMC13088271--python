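"""Simulator contracts: beat-train law, waveform landmarks, noise model,
and the generative BP relationship."""
import numpy as np
import pytest
from pydantic import ValidationError

from ppgecg import (
    SimConfig,
    add_noise,
    beat_annotations,
    generate_beat_train,
    generate_bp_truth,
    generate_cohort,
    generate_subject,
    synthesize_ecg,
    synthesize_ppg,
)
from ppgecg.core import ConfigurationError, InvalidAnnotationError
from ppgecg.siggen import _draw_ptts

from conftest import clean_config


class TestBeatTrain:
    @pytest.mark.parametrize("hr,expected_iv", [(60.0, 1.0), (120.0, 0.5)])
    def test_zero_variance_intervals_are_exact(self, hr, expected_iv):
        cfg = clean_config(hr_mean=hr, hr_sd=0.0)
        r = generate_beat_train(cfg)
        assert np.allclose(np.diff(r), expected_iv, atol=1e-9)

    def test_sixty_bpm_sixty_seconds_gives_sixty_beats(self):
        r = generate_beat_train(clean_config(hr_mean=60.0, hr_sd=0.0))
        assert abs(len(r) - 60) <= 1

    def test_interval_sample_mean_matches_truncated_normal(self):
        # Monte-Carlo check against the stated law: mean RR = 60/hr within
        # 3 standard errors (truncation bias is negligible at these settings).
        cfg = clean_config(duration_s=300.0, hr_mean=75.0, hr_sd=5.0, seed=7)
        iv = np.diff(generate_beat_train(cfg))
        mu, sd = 0.8, 5.0 * 60 / 75.0**2
        assert abs(iv.mean() - mu) < 3 * sd / np.sqrt(iv.size)

    def test_too_short_duration_yields_empty_train(self):
        assert generate_beat_train(clean_config(duration_s=0.3)).size == 0

    def test_strictly_increasing(self):
        r = generate_beat_train(clean_config(hr_sd=8.0, seed=5))
        assert np.all(np.diff(r) > 0)


class TestECG:
    def test_r_bump_is_global_argmax_per_beat(self):
        cfg = clean_config(duration_s=5.0, hr_mean=60.0, hr_sd=0.0)
        r = generate_beat_train(cfg)
        ecg = synthesize_ecg(r[:1], cfg)
        peak_t = np.argmax(ecg.samples) / cfg.fs
        assert abs(peak_t - r[0]) <= 1.0 / cfg.fs

    def test_empty_beats_give_zero_signal(self):
        cfg = clean_config(duration_s=2.0)
        ecg = synthesize_ecg(np.empty(0), cfg)
        assert len(ecg) == round(cfg.duration_s * cfg.fs)
        assert np.all(ecg.samples == 0)

    def test_r_amplitude_identical_across_beats(self):
        cfg = clean_config(hr_mean=60.0, hr_sd=0.0)
        r = generate_beat_train(cfg)
        ecg = synthesize_ecg(r, cfg)
        amps = [ecg.samples[int(round(t * cfg.fs))] for t in r[1:-1]]
        assert np.ptp(amps) < 1e-9

    def test_non_increasing_r_times_rejected(self):
        cfg = clean_config()
        with pytest.raises(InvalidAnnotationError):
            synthesize_ecg(np.array([1.0, 0.5]), cfg)


class TestPPG:
    def test_onset_minimum_at_r_plus_ptt(self):
        cfg = clean_config(duration_s=10.0, hr_mean=60.0, hr_sd=0.0, ptt_sd=0.0,
                           ptt_drift_amp=0.0, amp_mod_depth=0.0)
        r = generate_beat_train(cfg)
        ptts = np.full(r.size, 0.20)
        ppg = synthesize_ppg(r, ptts, cfg)
        for rt in r[1:-1]:
            onset_idx = int(round((rt + 0.20) * cfg.fs))
            w = ppg.samples[onset_idx - 50: onset_idx + 50]
            assert abs(int(np.argmin(w)) - 50) <= 1

    def test_zero_ptt_sd_gives_constant_lag(self):
        cfg = clean_config(ptt_sd=0.0, ptt_drift_amp=0.0)
        r = generate_beat_train(cfg)
        ann = beat_annotations(r, _draw_ptts(r, cfg), cfg)
        lags = [a.onset_time - a.r_time for a in ann]
        assert np.std(lags) < 1e-12

    def test_annotation_ordering_invariant(self):
        cfg = clean_config(hr_sd=6.0, seed=21)
        r = generate_beat_train(cfg)
        ann = beat_annotations(r, _draw_ptts(r, cfg), cfg)
        for a, b in zip(ann, ann[1:]):
            assert a.r_time < a.onset_time < a.peak_time < b.r_time

    @pytest.mark.parametrize("bad", [0.0, -0.1, 2.0])
    def test_invalid_ptt_rejected(self, bad):
        cfg = clean_config()
        r = np.array([1.0, 2.0, 3.0])
        with pytest.raises(InvalidAnnotationError):
            synthesize_ppg(r, np.array([0.2, bad, 0.2]), cfg)


class TestNoise:
    def test_all_zero_magnitudes_is_identity(self):
        cfg = clean_config()
        r = generate_beat_train(cfg)
        ecg = synthesize_ecg(r, cfg)
        out = add_noise(ecg, cfg)
        assert np.array_equal(out.samples, ecg.samples)

    def test_seeded_noise_is_reproducible(self):
        cfg = SimConfig(duration_s=30.0, seed=9)
        r = generate_beat_train(cfg)
        ecg = synthesize_ecg(r, cfg)
        a = add_noise(ecg, cfg, stream=2)
        b = add_noise(ecg, cfg, stream=2)
        assert np.array_equal(a.samples, b.samples)

    def test_gaussian_component_has_stated_sd(self):
        # Law-of-large-numbers check on the broadband term alone.
        cfg = SimConfig(duration_s=300.0, noise_gauss_sd=0.05,
                        noise_baseline_amp=0.0, artifact_rate=0.0, seed=13)
        base = synthesize_ecg(generate_beat_train(cfg), cfg)
        noisy = add_noise(base, cfg)
        resid = noisy.samples - base.samples
        assert abs(np.std(resid) - 0.05) < 0.02 * 0.05


class TestBPTruth:
    def test_noise_free_sbp_affine_in_inverse_ptt(self):
        rows = [(float(i), 0.15 + 0.01 * i, 0.8, 1.5, 0.15) for i in range(10)]
        bp = generate_bp_truth(rows, {"age": 30}, noise_sd=0.0)
        x = np.array([1.0 / r[1] for r in rows])
        s = np.array([b[1] for b in bp])
        resid = s - np.polyval(np.polyfit(x, s, 1), x)
        assert np.max(np.abs(resid)) < 1e-9

    def test_identical_features_identical_bp_at_zero_noise(self):
        rows = [(0.0, 0.2, 0.8, 1.5, 0.15), (5.0, 0.2, 0.8, 1.5, 0.15)]
        bp = generate_bp_truth(rows, {"age": 40}, noise_sd=0.0)
        assert bp[0][1:] == bp[1][1:]

    def test_inverse_ptt_drives_sbp_correlation(self):
        cohort = generate_cohort(6, seed=4, bp_noise_sd=3.0)
        inv_ptt, sbp = [], []
        for rec in cohort:
            for t, ptt, rr, pir, ts in rec.truth_features:
                inv_ptt.append(1.0 / ptt)
            for _, s, _ in rec.bp_ref:
                sbp.append(s)
        r = np.corrcoef(inv_ptt, sbp)[0, 1]
        assert r > 0.9

    def test_sbp_always_exceeds_dbp(self):
        rec = generate_subject(SimConfig(seed=17), bp_noise_sd=8.0)
        assert all(s > d for _, s, d in rec.bp_ref)

    def test_degenerate_coefficients_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_bp_truth(
                [(0.0, 0.2, 0.8, 1.5, 0.15)], {"age": 30},
                sbp_coeffs=(10.0, 0.0, 0.0, 0.0, 0.0),
                dbp_coeffs=(50.0, 0.0, 0.0, 0.0, 0.0),
                noise_sd=0.0,
            )


class TestDeterminismAndValidation:
    def test_identical_config_gives_bit_identical_subject(self):
        a = generate_subject(SimConfig(duration_s=30.0, seed=42))
        b = generate_subject(SimConfig(duration_s=30.0, seed=42))
        assert np.array_equal(a.ecg.samples, b.ecg.samples)
        assert np.array_equal(a.ppg.samples, b.ppg.samples)
        assert a.truth == b.truth
        assert a.bp_ref == b.bp_ref

    @pytest.mark.parametrize(
        "field,value",
        [("duration_s", -1.0), ("fs", 50.0), ("hr_mean", 250.0),
         ("ptt_mean", 1.5), ("noise_gauss_sd", -0.1)],
    )
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValidationError):
            SimConfig(**{field: value})
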