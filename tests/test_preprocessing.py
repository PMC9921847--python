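"""Waveform preprocessing: denoising, beat detection, NN filtering, resampling."""

import numpy as np
import pytest

import cardiokit as ck
from cardiokit.config import NNFilterParams
from cardiokit.datatypes import BeatSeries, RRSeries, WaveformRecord
from cardiokit.errors import ConfigurationError, ValidationError

from conftest import make_nn


def match_beats(detected, truth, window_s=0.05):
    """Greedy one-to-one matching of detected to true beat times."""
    used = set()
    matched = 0
    for t in truth:
        if detected.size == 0:
            break
        d = np.abs(detected - t)
        i = int(np.argmin(d))
        if d[i] <= window_s and i not in used:
            matched += 1
            used.add(i)
    return matched


class TestDenoise:
    def test_baseline_drift_attenuated(self):
        fs = 250.0
        t = np.arange(0, 10, 1 / fs)
        drift = np.sin(2 * np.pi * 0.2 * t)
        out = ck.denoise(WaveformRecord(drift, fs, "ECG"))
        assert np.sqrt(np.mean(out.samples**2)) <= 0.10 * np.sqrt(np.mean(drift**2))

    def test_passband_signal_preserved(self, rng):
        fs = 250.0
        t = np.arange(0, 10, 1 / fs)
        x = sum(np.sin(2 * np.pi * f * t + p) for f, p in [(5, 0.1), (9, 1.2), (15, 2.0)])
        out = ck.denoise(WaveformRecord(x, fs, "ECG"))
        r = np.corrcoef(x, out.samples)[0, 1]
        assert r >= 0.99

    def test_constant_signal_maps_to_zero(self):
        w = WaveformRecord(np.full(1000, 3.3), 250.0, "ECG")
        out = ck.denoise(w)
        assert np.max(np.abs(out.samples)) < 1e-6

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            ck.denoise(WaveformRecord(np.zeros(200) + np.arange(200), 60.0, "ECG"))


class TestDetectRPeaks:
    def test_noiseless_recovery_within_8ms(self):
        truth = np.arange(1, 61, 1.0)
        ecg = ck.generate_ecg(BeatSeries(beat_times_s=truth), fs_hz=250.0)
        det = ck.detect_r_peaks(ecg)
        assert len(det) == 60
        assert np.max(np.abs(det.beat_times_s - truth)) <= 0.008

    def test_noisy_sensitivity_and_precision(self):
        truth = np.arange(1, 61, 1.0)
        ecg = ck.generate_ecg(BeatSeries(beat_times_s=truth), fs_hz=250.0, snr_db=10.0, seed=7)
        det = ck.detect_r_peaks(ecg)
        matched = match_beats(det.beat_times_s, truth)
        sensitivity = matched / truth.size
        precision = matched / len(det)
        assert sensitivity >= 0.99
        assert precision >= 0.99

    def test_all_zero_signal_gives_empty_series(self):
        det = ck.detect_r_peaks(WaveformRecord(np.zeros(2500) + 1.0, 250.0, "ECG"))
        assert len(det) == 0

    def test_amplitude_scale_invariance(self):
        truth = np.arange(1, 31, 0.9)
        ecg = ck.generate_ecg(BeatSeries(beat_times_s=truth), fs_hz=250.0, snr_db=20.0, seed=3)
        a = ck.detect_r_peaks(ecg)
        b = ck.detect_r_peaks(WaveformRecord(ecg.samples * 137.0, 250.0, "ECG"))
        np.testing.assert_array_equal(a.beat_times_s, b.beat_times_s)

    def test_low_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            ck.detect_r_peaks(WaveformRecord(np.random.default_rng(0).normal(size=900), 90.0, "ECG"))

    def test_refractory_no_peaks_closer_than_200ms(self):
        truth = np.arange(1, 61, 0.4)
        ecg = ck.generate_ecg(BeatSeries(beat_times_s=truth), fs_hz=250.0, snr_db=10.0, seed=5)
        det = ck.detect_r_peaks(ecg)
        if len(det) > 1:
            assert np.min(np.diff(det.beat_times_s)) >= 0.2


class TestDetectPPGPeaks:
    def test_pp_intervals_match_spacing(self):
        truth = np.arange(1, 49, 0.8)
        ppg = ck.generate_ppg(BeatSeries(beat_times_s=truth), fs_hz=50.0)
        det = ck.detect_ppg_peaks(ppg)
        pp = np.diff(det.beat_times_s) * 1000.0
        assert np.all(np.abs(pp - 800.0) <= 10.0)

    def test_flat_signal_gives_empty_series(self):
        det = ck.detect_ppg_peaks(WaveformRecord(np.full(500, 2.0), 50.0, "PPG"))
        assert len(det) == 0

    def test_pp_vs_rr_consistency_on_shared_beats(self):
        spec = ck.RRGenSpec(duration_s=60, seed=11, broadband_sd_ms=20.0)
        synth = ck.generate_rr(spec)
        beats = BeatSeries(beat_times_s=synth.beat_times_s)
        ppg = ck.generate_ppg(beats, fs_hz=100.0)
        det = ck.detect_ppg_peaks(ppg)
        assert len(det) >= len(beats) - 1
        pp = np.diff(det.beat_times_s)[: len(beats) - 1] * 1000.0
        rr = np.diff(beats.beat_times_s)[: pp.size] * 1000.0
        assert np.mean(np.abs(pp - rr)) <= 15.0


class TestExtractRR:
    def test_differences(self):
        beats = BeatSeries(beat_times_s=np.array([0.0, 0.8, 1.65]))
        rr = ck.extract_rr(beats)
        np.testing.assert_allclose(rr.intervals_ms, [800.0, 850.0])

    def test_single_beat_rejected(self):
        with pytest.raises(ValidationError):
            ck.extract_rr(BeatSeries(beat_times_s=np.array([1.0])))

    def test_shape_law_and_cumsum_identity(self, rng):
        intervals = rng.uniform(500, 1100, 40)
        beats = BeatSeries(beat_times_s=np.cumsum(intervals) / 1000.0, origin_time_s=0.0)
        rr = ck.extract_rr(beats)
        assert len(rr) == 40
        np.testing.assert_allclose(rr.intervals_ms, intervals, atol=1e-9)


class TestFilterToNN:
    def test_inserted_outliers_rejected(self):
        vals = [800.0] * 10 + [400.0] + [800.0] * 5 + [1200.0] + [800.0] * 5
        rr = RRSeries(intervals_ms=vals, end_times_s=np.cumsum(vals) / 1000.0)
        nn = ck.filter_to_nn(rr)
        assert len(nn) == 20
        assert nn.n_rejected == 2
        assert np.all(nn.nn_intervals_ms == 800.0)

    def test_constant_series_unchanged(self):
        vals = np.full(30, 850.0)
        rr = RRSeries(intervals_ms=vals, end_times_s=np.cumsum(vals) / 1000.0)
        nn = ck.filter_to_nn(rr)
        assert len(nn) == 30 and nn.n_rejected == 0

    def test_physiologic_bound_overrides_neighbors(self):
        vals = np.array([150.0] * 5 + [160.0] * 5)
        rr = RRSeries(intervals_ms=vals, end_times_s=np.cumsum(vals) / 1000.0)
        with pytest.raises(ValidationError, match="no normal intervals"):
            ck.filter_to_nn(rr)

    def test_idempotent(self, rng):
        vals = rng.uniform(700, 900, 100)
        vals[20] = 250.0
        vals[60] = 1500.0
        rr = RRSeries(intervals_ms=vals, end_times_s=np.cumsum(vals) / 1000.0)
        once = ck.filter_to_nn(rr)
        twice = ck.filter_to_nn(
            RRSeries(intervals_ms=once.nn_intervals_ms, end_times_s=once.nn_end_times_s)
        )
        np.testing.assert_array_equal(once.nn_intervals_ms, twice.nn_intervals_ms)

    def test_rejection_splits_segments(self):
        vals = [800.0] * 10 + [400.0] + [800.0] * 10
        rr = RRSeries(intervals_ms=vals, end_times_s=np.cumsum(vals) / 1000.0)
        nn = ck.filter_to_nn(rr)
        assert nn.segment_ids.max() == 1  # two segments around the gap


class TestResampleTachogram:
    def test_constant_series_exact(self):
        nn = make_nn(np.full(20, 800.0))
        tach = ck.resample_tachogram(nn)
        np.testing.assert_allclose(tach.values_ms, 800.0, atol=1e-9)
        assert tach.rate_hz == 2.0

    def test_sinusoidal_modulation_peak_recovered(self):
        spec = ck.RRGenSpec(
            duration_s=300,
            seed=0,
            lf_tone=ck.ToneSpec(0.10, 50.0),
            hf_tone=ck.ToneSpec(0.25, 0.0),
            broadband_sd_ms=0.0,
        )
        tach = ck.resample_tachogram(ck.generate_rr(spec).as_nn_series())
        x = tach.values_ms - tach.values_ms.mean()
        freqs = np.fft.rfftfreq(x.size, d=0.5)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        assert abs(peak - 0.10) <= 0.01

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValidationError):
            ck.resample_tachogram(make_nn([800.0, 820.0, 810.0]))

    def test_no_extrapolation_beyond_span(self):
        nn = make_nn(np.full(10, 800.0))
        tach = ck.resample_tachogram(nn)
        assert tach.times_s[-1] <= nn.nn_end_times_s[-1] + 1e-12
        assert tach.times_s[0] >= nn.nn_end_times_s[0] - 1e-12
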