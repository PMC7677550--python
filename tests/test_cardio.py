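import warnings

import numpy as np
import pytest

from vrstress.cardio import (
    BeatSeries,
    NNSeries,
    clean_rr,
    decimate_signal,
    default_segments,
    detect_r_peaks,
    heart_rate,
    hrv_ti,
    nn_from_beats,
    respiration_rate,
    rmssd,
    sdnn,
    segment_summary,
)
from vrstress.core import EcgSignal, RespSignal
from vrstress.errors import InsufficientDataError, InvalidArgumentError
from vrstress.synth import simulate_respiration, simulate_rr_series, synthesize_ecg
from vrstress.synth.traits import TraitProfile


# ---------------------------------------------------- independent oracles
def oracle_rmssd(x):
    x = np.asarray(x, dtype=float)
    acc = 0.0
    for i in range(len(x) - 1):
        acc += (x[i + 1] - x[i]) ** 2
    return (acc / (len(x) - 1)) ** 0.5


def oracle_sdnn(x):
    x = np.asarray(x, dtype=float)
    m = sum(x) / len(x)
    return (sum((xi - m) ** 2 for xi in x) / (len(x) - 1)) ** 0.5


def oracle_hrv_ti(x):
    x = np.asarray(x, dtype=float)
    counts = {}
    for xi in x:
        b = int(xi // (1000.0 / 128.0))
        counts[b] = counts.get(b, 0) + 1
    return len(x) / max(counts.values())


def oracle_hr(x):
    x = np.asarray(x, dtype=float)
    return 60000.0 / (sum(x) / len(x))


def _nn(intervals):
    intervals = np.asarray(intervals, dtype=float)
    onsets = np.concatenate([[0.0], np.cumsum(intervals[:-1]) / 1000.0])
    return NNSeries(
        intervals=intervals,
        artifact_flags=np.zeros(intervals.size, dtype=bool),
        onset_times=onsets,
    )


# ----------------------------------------------------------------- decimate
class TestDecimate:
    def test_factor_validation(self):
        sig = EcgSignal(samples=np.zeros(1000), fs=1000.0)
        with pytest.raises(InvalidArgumentError):
            decimate_signal(sig, 0)

    def test_identity(self):
        sig = EcgSignal(samples=np.sin(np.arange(1000) * 0.01), fs=1000.0)
        out = decimate_signal(sig, 1)
        np.testing.assert_array_equal(out.samples, sig.samples)
        assert out.fs == 1000.0

    def test_1000_to_500(self):
        sig = EcgSignal(samples=np.random.default_rng(0).normal(size=4000),
                        fs=1000.0)
        out = decimate_signal(sig, 2)
        assert out.fs == 500.0
        assert out.n == 2000

    def test_passband_amplitude_preserved(self):
        t = np.arange(0, 10, 1 / 1000)
        sig = EcgSignal(samples=np.sin(2 * np.pi * 5.0 * t), fs=1000.0)
        out = decimate_signal(sig, 2)
        mid = out.samples[200:-200]
        assert abs(mid.max() - 1.0) < 0.01

    @pytest.mark.parametrize("freq", [5.0, 50.0, 100.0])
    def test_amplitude_below_04_nyquist(self, freq):
        t = np.arange(0, 10, 1 / 1000)
        sig = EcgSignal(samples=np.sin(2 * np.pi * freq * t), fs=1000.0)
        out = decimate_signal(sig, 2)  # new Nyquist 250 Hz; 0.4x = 100 Hz
        mid = out.samples[200:-200]
        # amplitude via RMS: peak sampling on the coarser grid is biased
        amplitude = np.sqrt(2 * np.mean(mid**2))
        assert abs(amplitude - 1.0) < 0.01


# ------------------------------------------------------------------ r-peaks
def _profile(**kw):
    base = dict(
        vulnerability=0.0, thigmotaxis_bias=0.5, center_avoidance=0.5,
        gait_speed_cv=0.2, mean_nn=800.0, nn_sd=40.0, rsa_amplitude=20.0,
        resp_rate=15.0,
    )
    base.update(kw)
    return TraitProfile(**base)


class TestDetectRPeaks:
    def test_high_snr_accuracy(self):
        beats = np.arange(0.5, 59.0, 1.0)
        ecg, _ = synthesize_ecg(beats, 500.0, snr_db=np.inf, seed=0, duration=60.0)
        det = detect_r_peaks(ecg)
        assert det.n == beats.size
        np.testing.assert_allclose(det.r_times, beats, atol=0.010)

    def test_flat_signal_warns_empty(self):
        ecg = EcgSignal(samples=np.zeros(5000), fs=500.0)
        with pytest.warns(UserWarning):
            det = detect_r_peaks(ecg)
        assert det.n == 0

    def test_beat_count_750ms(self):
        prof = _profile(mean_nn=750.0, nn_sd=0.0, rsa_amplitude=0.0)
        beats, _ = simulate_rr_series(prof, 90.0, seed=0)
        ecg, _ = synthesize_ecg(beats, 500.0, snr_db=20.0, seed=0, duration=90.0)
        det = detect_r_peaks(ecg)
        assert abs(det.n - 120) <= 1

    def test_preconditions(self):
        with pytest.raises(InvalidArgumentError):
            detect_r_peaks(EcgSignal(samples=np.zeros(1000), fs=200.0))
        with pytest.raises(InvalidArgumentError):
            detect_r_peaks(EcgSignal(samples=np.zeros(500), fs=500.0))


# ----------------------------------------------------------------- clean_rr
class TestCleanRR:
    def test_constant_series_unchanged(self):
        beats = BeatSeries(r_times=np.arange(10) * 0.8)
        nn = clean_rr(beats)
        assert not nn.artifact_flags.any()
        np.testing.assert_allclose(nn.intervals, 800.0)

    def test_single_outlier_interpolated(self):
        rng = np.random.default_rng(0)
        intervals = 800.0 + rng.uniform(-10, 10, size=40)
        intervals[20] = 3000.0
        beats = BeatSeries(r_times=np.concatenate([[0.0], np.cumsum(intervals)]) / 1000.0)
        nn = clean_rr(beats)
        assert nn.artifact_flags[20]
        assert nn.artifact_flags.sum() == 1
        expected = (nn.intervals[19] + nn.intervals[21]) / 2
        assert nn.intervals[20] == pytest.approx(expected, abs=1e-6)
        assert abs(nn.intervals[20] - 800.0) < 15.0

    def test_two_outliers_single_pass(self):
        # brute-force rule application: both flagged against raw moments
        intervals = np.full(30, 800.0)
        intervals[5] += 5.0
        intervals[25] -= 5.0
        intervals[10] = 2500.0
        intervals[18] = 2600.0
        mean, sd = intervals.mean(), intervals.std(ddof=1)
        expect_flags = np.abs(intervals - mean) > 3 * sd
        beats = BeatSeries(r_times=np.concatenate([[0.0], np.cumsum(intervals)]) / 1000.0)
        nn = clean_rr(beats)
        np.testing.assert_array_equal(nn.artifact_flags, expect_flags)
        assert expect_flags[10] and expect_flags[18]

    def test_endpoint_outlier_nearest_value(self):
        intervals = np.full(20, 800.0)
        intervals[3] += 2.0
        intervals[0] = 3000.0
        beats = BeatSeries(r_times=np.concatenate([[0.0], np.cumsum(intervals)]) / 1000.0)
        nn = clean_rr(beats)
        assert nn.artifact_flags[0]
        assert nn.intervals[0] == nn.intervals[1]

    def test_too_few_beats(self):
        with pytest.raises(InsufficientDataError):
            clean_rr(BeatSeries(r_times=np.array([0.0, 0.8, 1.6])))

    def test_idempotent_on_clean_tailed_series(self):
        # bounded jitter plus one artifact: the second pass changes nothing
        rng = np.random.default_rng(1)
        z = np.clip(rng.normal(size=60), -2.0, 2.0)
        intervals = 800.0 + 8.0 * z
        intervals[30] = 2400.0
        beats = BeatSeries(r_times=np.concatenate([[0.0], np.cumsum(intervals)]) / 1000.0)
        once = clean_rr(beats)
        twice = clean_rr(once)
        np.testing.assert_array_equal(once.intervals, twice.intervals)


# ------------------------------------------------------------------ metrics
class TestMetrics:
    def test_rmssd_examples(self):
        assert rmssd(_nn([800, 800, 800])) == 0.0
        assert rmssd(_nn([800, 810, 800])) == pytest.approx(10.0)
        assert rmssd(_nn([800, 820, 800, 820])) == pytest.approx(20.0)

    def test_sdnn_examples(self):
        assert sdnn(_nn([800, 800])) == 0.0
        assert sdnn(_nn([700, 900])) == pytest.approx(141.42, abs=0.01)

    def test_shift_invariance(self):
        x = np.array([700.0, 820.0, 760.0, 801.0, 777.0])
        assert rmssd(x + 50) == pytest.approx(rmssd(x))
        assert sdnn(x + 50) == pytest.approx(sdnn(x))
        assert heart_rate(x + 50) == pytest.approx(60000.0 / (np.mean(x) + 50))

    def test_hrv_ti_examples(self):
        assert hrv_ti(_nn([800.0] * 30)) == 1.0
        # 30 intervals spread over 3 distinct bins, 10 each
        vals = [801.0] * 10 + [809.0] * 10 + [817.0] * 10
        assert hrv_ti(_nn(vals)) == pytest.approx(3.0)

    def test_hrv_ti_general_formula(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(600, 1000, size=200)
        assert hrv_ti(x) == pytest.approx(oracle_hrv_ti(x))

    def test_heart_rate_examples(self):
        assert heart_rate(_nn([1000.0] * 10)) == pytest.approx(60.0)
        assert heart_rate(_nn([500.0] * 10)) == pytest.approx(120.0)
        assert heart_rate(np.array([600.0, 1000.0])) == pytest.approx(75.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            rmssd(np.array([800.0, 810.0]))
        with pytest.raises(InsufficientDataError):
            sdnn(np.array([800.0]))
        with pytest.raises(InsufficientDataError):
            hrv_ti(np.array([800.0]))

    def test_oracle_agreement_random_series(self):
        # 200 series here; the full 1000-series sweep lives in acceptance
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(5, 200)
            x = rng.uniform(400, 1200, size=n)
            assert rmssd(x) == pytest.approx(oracle_rmssd(x), rel=1e-9)
            assert sdnn(x) == pytest.approx(oracle_sdnn(x), rel=1e-9)
            assert hrv_ti(x) == pytest.approx(oracle_hrv_ti(x), rel=1e-9)
            assert heart_rate(x) == pytest.approx(oracle_hr(x), rel=1e-9)


# ------------------------------------------------------------- respiration
class TestRespirationRate:
    def test_clean_sinusoid(self):
        w = simulate_respiration(15.0, 90.0, 100.0, noise_sd=0.0, seed=0)
        assert respiration_rate(w) == pytest.approx(15.0, abs=0.7)

    def test_below_band_missing(self):
        t = np.arange(0, 90, 1 / 100)
        w = RespSignal(samples=np.sin(2 * np.pi * 0.05 * t), fs=100.0)
        with pytest.warns(UserWarning):
            rate = respiration_rate(w)
        assert np.isnan(rate)

    def test_preconditions(self):
        with pytest.raises(InvalidArgumentError):
            respiration_rate(RespSignal(samples=np.zeros(100), fs=10.0))
        with pytest.raises(InvalidArgumentError):
            respiration_rate(RespSignal(samples=np.zeros(100), fs=100.0))

    def test_sweep_recovery(self):
        for rate in (12, 18, 26, 34, 40):
            w = simulate_respiration(float(rate), 90.0, 100.0, 0.05, seed=rate)
            assert respiration_rate(w) == pytest.approx(rate, abs=0.5)


# ------------------------------------------------------------ segmentation
class TestSegmentSummary:
    def _series(self, duration=90.0, mean_nn=800.0):
        prof = _profile(mean_nn=mean_nn)
        beats, _ = simulate_rr_series(prof, duration, seed=7)
        return clean_rr(BeatSeries(r_times=beats))

    def test_default_three_blocks(self):
        segs = default_segments(90.0, 30.0)
        assert segs == [(0.0, 30.0), (30.0, 60.0), (60.0, 90.0)]
        out = segment_summary(self._series(), None, segs)
        assert len(out) == 3
        assert all(not s.missing for s in out)

    def test_single_segment_equals_whole(self):
        nn = self._series()
        [whole] = segment_summary(nn, None, [(0.0, 90.0)])
        assert whole.rmssd == pytest.approx(rmssd(nn))
        assert whole.sdnn == pytest.approx(sdnn(nn))
        assert whole.hr == pytest.approx(heart_rate(nn))

    def test_sparse_block_flagged_missing(self):
        nn = self._series()
        out = segment_summary(nn, None, [(0.0, 1.0)])
        assert out[0].missing
        assert np.isnan(out[0].rmssd)

    def test_empty_segments_rejected(self):
        with pytest.raises(InvalidArgumentError):
            segment_summary(self._series(), None, [])

    def test_respiration_per_segment(self):
        nn = self._series()
        resp = simulate_respiration(15.0, 90.0, 100.0, 0.0, seed=0)
        [whole] = segment_summary(nn, resp, [(0.0, 90.0)])
        assert whole.rr == pytest.approx(15.0, abs=0.7)
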