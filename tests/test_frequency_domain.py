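"""Spectral estimation (Burg, Welch, wavelet) and band powers."""

import numpy as np
import pytest

import cardiokit as ck
from cardiokit.datatypes import ARModel, RRSeries, UniformTachogram
from cardiokit.errors import QualityError, ValidationError

from conftest import make_nn


def ar1_series(a: float, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    e = rng.normal(size=n)
    x = np.zeros(n)
    for t in range(1, n):
        x[t] = a * x[t - 1] + e[t]
    return x


def tone_tachogram(tones, duration_s=600.0, rate_hz=2.0, base=800.0):
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    vals = base + sum(amp * np.sin(2 * np.pi * f * t) for f, amp in tones)
    return UniformTachogram(values_ms=vals, rate_hz=rate_hz)


def yule_walker_ar1(x: np.ndarray) -> float:
    """Lag-1 autocorrelation oracle for the AR(1) coefficient."""
    x = x - x.mean()
    return float(np.dot(x[1:], x[:-1]) / np.dot(x, x))


class TestSelectSegment:
    def test_windowing(self):
        nn = make_nn(np.full(1000, 800.0))
        seg = ck.select_segment(nn, 0.0, 300.0)
        assert seg.nn_end_times_s[-1] < 300.0
        assert len(seg) < 1000

    def test_start_beyond_record_rejected(self):
        with pytest.raises(ValidationError):
            ck.select_segment(make_nn(np.full(100, 800.0)), 500.0)

    def test_excess_rejection_raises_quality_error(self):
        vals = np.full(400, 800.0)
        nn = make_nn(vals)
        # simulate 15% of beats in the window having been rejected upstream
        nn.n_rejected = 60
        nn.rejected_times_s = np.linspace(1.0, 299.0, 60)
        with pytest.raises(QualityError, match="%"):
            ck.select_segment(nn, 0.0, 300.0)


class TestFitBurg:
    def test_ar1_coefficient_recovery_vs_yule_walker(self):
        x = ar1_series(0.5, 4096, seed=42)
        tach = UniformTachogram(values_ms=x, rate_hz=2.0)
        model = ck.fit_burg(tach, order=1)
        assert model.coefficients[0] == pytest.approx(-0.5, abs=0.05)
        # agreement with the independent Yule-Walker route on the same data
        assert model.coefficients[0] == pytest.approx(-yule_walker_ar1(x), abs=0.01)

    def test_order_zero_epsilon_is_sample_variance(self, rng):
        x = rng.normal(size=1000)
        model = ck.fit_burg(UniformTachogram(values_ms=x, rate_hz=2.0), order=0)
        assert model.epsilon == pytest.approx(np.var(x), rel=1e-12)

    @pytest.mark.parametrize("order", [4, 8, 16])
    def test_fitted_model_always_stable(self, order, rng):
        x = ar1_series(0.9, 600, seed=1) + rng.normal(0, 0.1, 600)
        model = ck.fit_burg(UniformTachogram(values_ms=x, rate_hz=2.0), order=order)
        assert np.all(np.abs(model.poles) < 1.0)

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            ck.fit_burg(UniformTachogram(values_ms=np.arange(20.0), rate_hz=2.0), order=16)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            ck.fit_burg(UniformTachogram(values_ms=np.full(100, 5.0), rate_hz=2.0), order=4)


class TestPsdBurg:
    def test_white_noise_closed_form(self):
        model = ARModel(order=0, coefficients=np.empty(0), epsilon=1.0, fs=2.0)
        est = ck.psd_burg(model)
        inner = est.psd[1:-1]
        np.testing.assert_allclose(inner, 1.0, rtol=1e-12)
        assert np.trapezoid(est.psd, est.freqs_hz) == pytest.approx(1.0, rel=1e-3)

    def test_matches_closed_form_ar2_spectrum(self):
        a = np.array([-0.75, 0.5])
        model = ARModel(order=2, coefficients=a, epsilon=2.0, fs=2.0)
        est = ck.psd_burg(model, n_freqs=512)
        f = est.freqs_hz
        denom = np.abs(1 + a[0] * np.exp(-2j * np.pi * f / 2.0)
                       + a[1] * np.exp(-4j * np.pi * f / 2.0)) ** 2
        expected = 2.0 / 2.0 / denom * 2.0
        expected[0] /= 2.0
        expected[-1] /= 2.0
        np.testing.assert_allclose(est.psd, expected, rtol=1e-9)

    def test_integral_approximates_variance(self):
        x = ar1_series(0.6, 4096, seed=3)
        tach = UniformTachogram(values_ms=x, rate_hz=2.0)
        est = ck.psd_burg(ck.fit_burg(tach, order=8), n_freqs=4096)
        integral = np.trapezoid(est.psd, est.freqs_hz)
        assert integral == pytest.approx(np.var(x), rel=0.05)


class TestPsdWelch:
    def test_sinusoid_power_and_location(self):
        tach = tone_tachogram([(0.1, 50.0)], duration_s=300.0)
        est = ck.psd_welch(tach)
        peak_f = est.freqs_hz[np.argmax(est.psd)]
        resolution = est.freqs_hz[1] - est.freqs_hz[0]
        assert abs(peak_f - 0.1) <= resolution
        total = np.trapezoid(est.psd, est.freqs_hz)
        assert total == pytest.approx(1250.0, rel=0.10)

    def test_white_noise_flat_under_averaging(self):
        ratios = []
        for seed in range(10):
            x = np.random.default_rng(seed).normal(0, 30, 2400)
            est = ck.psd_welch(UniformTachogram(values_ms=x, rate_hz=2.0), window_s=60.0)
            band = est.psd[(est.freqs_hz > 0.02) & (est.freqs_hz < 0.98)]
            ratios.append(band.max() / band.min())
        assert np.mean(ratios) < 3.0

    def test_zero_signal_zero_psd(self):
        est = ck.psd_welch(UniformTachogram(values_ms=np.zeros(600), rate_hz=2.0))
        assert np.all(est.psd == 0.0)

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValidationError):
            ck.psd_welch(UniformTachogram(values_ms=np.zeros(100), rate_hz=2.0), window_s=300.0)


class TestPsdWavelet:
    def test_tone_localization(self):
        tach = tone_tachogram([(0.1, 50.0)])
        est = ck.psd_wavelet(tach)
        peak_f = est.freqs_hz[np.argmax(est.psd)]
        assert abs(peak_f - 0.1) <= 0.01

    def test_white_noise_band_ratio_close_to_welch(self):
        cfg = ck.AnalysisConfig()
        diffs = []
        for seed in range(3):
            x = np.random.default_rng(seed).normal(0, 30, 1200)
            tach = UniformTachogram(values_ms=x, rate_hz=2.0)
            r_w = ck.band_powers(ck.psd_welch(tach), cfg, 600.0).lf_hf_ratio
            r_v = ck.band_powers(ck.psd_wavelet(tach), cfg, 600.0).lf_hf_ratio
            diffs.append(abs(r_v - r_w) / r_w)
        assert np.mean(diffs) <= 0.25

    def test_zero_signal_zero_spectrum(self):
        est = ck.psd_wavelet(UniformTachogram(values_ms=np.zeros(600), rate_hz=2.0))
        assert np.all(est.psd == 0.0)

    def test_short_record_rejected(self):
        with pytest.raises(ValidationError):
            ck.psd_wavelet(UniformTachogram(values_ms=np.zeros(32), rate_hz=2.0))


class TestBandPowers:
    def test_single_lf_tone_localized(self):
        tach = tone_tachogram([(0.1, 50.0)])
        idx = ck.band_powers(ck.psd_welch(tach), record_duration_s=600.0)
        assert idx.lf_ms2 >= 0.95 * idx.total_power_ms2
        assert idx.lf_nu >= 0.95

    def test_equal_tones_unit_ratio(self):
        tach = tone_tachogram([(0.1, 50.0), (0.25, 50.0)])
        idx = ck.band_powers(ck.psd_welch(tach), record_duration_s=600.0)
        assert idx.lf_hf_ratio == pytest.approx(1.0, abs=0.1)
        assert idx.lf_nu + idx.hf_nu == pytest.approx(1.0)

    def test_zero_hf_reports_absent_ratio_with_warning(self):
        est = ck.SpectralEstimate(
            freqs_hz=np.linspace(0, 1, 256),
            psd=np.where(np.linspace(0, 1, 256) < 0.12, 100.0, 0.0),
            method="welch",
        )
        with pytest.warns(UserWarning):
            idx = ck.band_powers(est, record_duration_s=300.0)
        assert idx.lf_hf_ratio is None

    def test_bands_partition_total_power(self, rng):
        x = rng.normal(0, 30, 1200)
        est = ck.psd_welch(UniformTachogram(values_ms=x, rate_hz=2.0))
        idx = ck.band_powers(est, record_duration_s=600.0)
        parts = idx.ulf_ms2 or 0.0
        parts += idx.vlf_ms2 + idx.lf_ms2 + idx.hf_ms2
        assert idx.total_power_ms2 >= parts - 1e-9
        assert idx.total_power_ms2 == pytest.approx(parts, rel=0.02)

    def test_ulf_absent_for_short_records(self):
        tach = tone_tachogram([(0.1, 30.0)], duration_s=300.0)
        idx = ck.band_powers(ck.psd_welch(tach), record_duration_s=300.0)
        assert idx.ulf_ms2 is None

    def test_burg_lf_hf_recovery_grid(self):
        """Burg-estimated LF/HF tracks known tone-power ratios with small bias."""
        cfg = ck.AnalysisConfig()
        t = np.arange(0.0, 600.0, 0.5)
        for lf_amp, hf_amp in [(50, 50), (70, 35), (35, 70), (60, 42), (42, 60)]:
            truth = (lf_amp / hf_amp) ** 2
            errs = []
            for seed in range(5):
                vals = (800.0 + lf_amp * np.sin(2 * np.pi * 0.1 * t)
                        + hf_amp * np.sin(2 * np.pi * 0.25 * t)
                        + np.random.default_rng(seed).normal(0, 10.0, t.size))
                tach = UniformTachogram(values_ms=vals, rate_hz=2.0)
                est = ck.psd_burg(ck.fit_burg(tach, cfg.burg_order))
                errs.append(ck.band_powers(est, cfg, 600.0).lf_hf_ratio / truth - 1.0)
            assert abs(np.mean(errs)) < 0.15, (lf_amp, hf_amp)

    def test_burg_welch_total_power_agreement(self):
        x = ar1_series(0.5, 600, seed=9)
        tach = UniformTachogram(values_ms=x, rate_hz=2.0)
        tp_b = ck.band_powers(ck.psd_burg(ck.fit_burg(tach, 4)), record_duration_s=300.0)
        tp_w = ck.band_powers(ck.psd_welch(tach, window_s=150.0), record_duration_s=300.0)
        assert tp_b.total_power_ms2 == pytest.approx(tp_w.total_power_ms2, rel=0.20)
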