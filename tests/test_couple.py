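"""Weighted superposition, R-anchored fiducials, and beat features."""
import numpy as np
import pytest

from ppgecg import (
    CoupleParams,
    RPeakList,
    RunConfig,
    TimeSeries,
    compute_beat_features,
    couple_signals,
    detect_fiducials_coupled,
    process_subject,
)
from ppgecg.core import AlignmentError, FiducialSet


class TestCoupleSignals:
    def test_weighted_sum_sample_for_sample(self):
        ppg = TimeSeries(np.array([0.4, 0.4]), 500.0)
        ecg = TimeSeries(np.array([0.8, 0.0]), 500.0)
        out = couple_signals(ppg, ecg, CoupleParams(alpha=0.5, beta=1.0))
        np.testing.assert_allclose(out.samples, [1.0, 0.2])

    def test_zero_ecg_segment_is_half_ppg(self):
        rng = np.random.default_rng(1)
        ppg = TimeSeries(rng.normal(size=1000), 500.0)
        ecg = TimeSeries(np.zeros(1000), 500.0)
        out = couple_signals(ppg, ecg, CoupleParams(alpha=0.5, beta=1.0))
        np.testing.assert_array_equal(out.samples, 0.5 * ppg.samples)

    def test_degenerate_weights_reproduce_ecg(self):
        rng = np.random.default_rng(2)
        ppg = TimeSeries(rng.normal(size=1000), 500.0)
        ecg = TimeSeries(rng.normal(size=1000), 500.0)
        out = couple_signals(ppg, ecg, CoupleParams(alpha=1e-12, beta=1.0))
        np.testing.assert_allclose(out.samples, ecg.samples, atol=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            couple_signals(
                TimeSeries(np.zeros(10), 500.0), TimeSeries(np.zeros(11), 500.0)
            )

    def test_coupling_commutes_with_cropping(self):
        rng = np.random.default_rng(3)
        p, e = rng.normal(size=2000), rng.normal(size=2000)
        params = CoupleParams()
        full = couple_signals(TimeSeries(p, 500.0), TimeSeries(e, 500.0), params)
        crop = couple_signals(
            TimeSeries(p[500:1500], 500.0), TimeSeries(e[500:1500], 500.0), params
        )
        np.testing.assert_array_equal(full.samples[500:1500], crop.samples)


class TestDetectFiducials:
    def test_search_window_is_paper_rule(self):
        # RR = 1 s anchored at t = 10 s: the onset must come from
        # [10.1, 10.9]. Place the signal minimum outside that window and a
        # secondary dip inside; the detector must return the in-window dip.
        fs = 500.0
        n = int(12 * fs)
        x = np.ones(n)
        x[int(10.05 * fs)] = -5.0  # deeper, but outside the window
        # in-window pulse: falls to a foot at 10.3 then rises
        t = np.arange(int(10.1 * fs), int(10.9 * fs)) / fs
        x[int(10.1 * fs): int(10.9 * fs)] = np.abs(t - 10.3) * 4.0
        peaks = RPeakList(np.array([int(10.0 * fs), int(11.0 * fs)]), fs)
        fid = detect_fiducials_coupled(TimeSeries(x, fs), peaks)
        assert fid.onset_times[0] == pytest.approx(10.3, abs=2 / fs)

    def test_flat_window_flagged_missing(self):
        fs = 500.0
        x = np.zeros(int(3 * fs))
        peaks = RPeakList(np.array([int(0.5 * fs), int(1.5 * fs)]), fs)
        fid = detect_fiducials_coupled(TimeSeries(x, fs), peaks)
        assert len(fid) == 1 and not np.isfinite(fid.onset_times[0])

    def test_fewer_than_two_r_peaks_gives_empty_set(self):
        fid = detect_fiducials_coupled(
            TimeSeries(np.zeros(5000), 500.0), RPeakList(np.array([100]), 500.0)
        )
        assert len(fid) == 0

    def test_window_containment_invariant(self, noisy_subject, runcfg):
        res = process_subject(noisy_subject, runcfg)
        fid = res.fid_coupled
        m = np.isfinite(fid.onset_times)
        rr = fid.next_r_times[m] - fid.r_times[m]
        rel = fid.onset_times[m] - fid.r_times[m]
        assert np.all(rel >= 0.1 * rr - 1e-9)
        assert np.all(rel <= 0.9 * rr + 1e-9)


class TestCleanSignalOracle:
    """Primary end-to-end correctness oracle: zero-noise recovery."""

    def test_every_fiducial_recovered_within_one_sample(self, clean_subject, runcfg):
        res = process_subject(clean_subject, runcfg, filtered=False)
        fid = res.fid_coupled
        fs = clean_subject.ecg.fs
        truth = {round(a.r_time * fs): a for a in clean_subject.truth}
        checked = 0
        for k in range(len(fid)):
            a = truth.get(round(fid.r_times[k] * fs))
            assert a is not None, "detected beat with no matching truth R"
            assert np.isfinite(fid.onset_times[k]) and np.isfinite(fid.peak_times[k])
            assert abs(fid.onset_times[k] - a.onset_time) <= 1.0 / fs + 1e-9
            assert abs(fid.peak_times[k] - a.peak_time) <= 1.0 / fs + 1e-9
            checked += 1
        assert checked == len(clean_subject.truth) - 1

    def test_r_times_on_coupled_equal_ecg_r_times(self, clean_subject, runcfg):
        # Temporal-alignment invariant: the coupled signal preserves the
        # ECG phase, so per-cycle argmax matches the original R sample.
        res = process_subject(clean_subject, runcfg, filtered=False)
        ecg = clean_subject.ecg
        for i in res.peaks.r_indices[1:-1]:
            lo, hi = i - 50, i + 50
            a = int(np.argmax(res.coupled.samples[lo:hi]))
            b = int(np.argmax(ecg.samples[lo:hi]))
            # The PPG component can tilt two near-equal-height R samples,
            # so agreement is to the sample grid (one sample = 2 ms).
            assert abs(a - b) <= 1


class TestBeatFeatures:
    def _fid(self):
        return FiducialSet(
            onset_times=np.array([10.20]),
            peak_times=np.array([10.35]),
            source_method="coupled",
            r_times=np.array([10.0]),
            next_r_times=np.array([11.0]),
        )

    def test_interval_arithmetic(self):
        fs = 500.0
        x = np.ones(int(12 * fs))
        x[int(10.20 * fs)] = 1.0
        x[int(10.35 * fs)] = 2.0
        feats, skipped = compute_beat_features(
            self._fid(), TimeSeries(x, fs), CoupleParams(alpha=1.0, beta=1.0)
        )
        assert skipped == 0
        b = feats[0]
        assert b.rr == pytest.approx(1.0)
        assert b.ptt == pytest.approx(0.20)
        assert b.t_sys == pytest.approx(0.15)
        assert b.pir == pytest.approx(2.0)

    def test_nonpositive_onset_amplitude_skips_beat(self):
        fs = 500.0
        x = np.full(int(12 * fs), -1.0)
        feats, skipped = compute_beat_features(
            self._fid(), TimeSeries(x, fs), CoupleParams(alpha=1.0, beta=1.0)
        )
        assert feats == [] and skipped == 1

    def test_clean_pipeline_recovers_mean_ptt(self, clean_subject, runcfg):
        res = process_subject(clean_subject, runcfg, filtered=False)
        est = np.mean([b.ptt for b in res.beats])
        true = np.mean([a.ptt for a in clean_subject.truth[:-1]])
        assert abs(est - true) <= 0.002
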