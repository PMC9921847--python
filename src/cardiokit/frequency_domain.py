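"""Frequency-domain HRV analysis.

Spectral estimation on the uniform tachogram by three routes:

* Burg autoregressive modelling — the lattice recursion choosing each
  reflection coefficient to minimize the summed forward+backward prediction
  error; the fitted model is always stable.  The PSD is
  ``P(f) = (eps_p / fs) / |1 + sum_k a_k e^(-2*pi*j*k*f/fs)|^2`` doubled for
  0 < f < fs/2 (one-sided), so its integral over [0, fs/2] equals the
  process variance.
* Welch averaged periodogram (scipy), density-scaled the same way.
* Global wavelet spectrum — the time-average of the Morlet scalogram,
  rescaled by a single variance-matching constant so band integrals are
  comparable to Welch.

Band powers integrate the PSD over the canonical ULF/VLF/LF/HF intervals by
the trapezoid rule; normalized units are fractions lf/(lf+hf), hf/(lf+hf).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .datatypes import (
    ARModel,
    FrequencyDomainIndices,
    NNSeries,
    SpectralEstimate,
    UniformTachogram,
)
from .errors import QualityError, ValidationError

logger = logging.getLogger("cardiokit")


def select_segment(
    nn: NNSeries, start_s: float, length_s: float = 300.0
) -> NNSeries:
    """Slice the NN intervals whose end times fall in [start, start+length).

    Fails when the window lies outside the record span or when more than 10%
    of the beats in the window were rejected during NN filtering.
    """
    if length_s <= 0:
        raise ValidationError("segment length must be positive")
    t_begin, t_end = nn.start_time_s, float(nn.nn_end_times_s[-1])
    if start_s < t_begin - 1e-9 or start_s >= t_end:
        raise ValidationError(
            f"segment start {start_s} s outside record span [{t_begin}, {t_end}] s"
        )
    hi = start_s + length_s
    mask = (nn.nn_end_times_s >= start_s) & (nn.nn_end_times_s < hi)
    if not np.any(mask):
        raise ValidationError("segment contains no NN intervals")
    n_rej = int(np.sum((nn.rejected_times_s >= start_s) & (nn.rejected_times_s < hi)))
    n_tot = int(np.sum(mask)) + n_rej
    frac = n_rej / n_tot if n_tot else 0.0
    if frac > 0.10:
        raise QualityError(
            f"segment rejection fraction {frac:.1%} exceeds 10%", rejection_fraction=frac
        )
    return NNSeries(
        nn_intervals_ms=nn.nn_intervals_ms[mask],
        nn_end_times_s=nn.nn_end_times_s[mask],
        segment_ids=nn.segment_ids[mask],
        n_rejected=n_rej,
        rejected_times_s=nn.rejected_times_s[
            (nn.rejected_times_s >= start_s) & (nn.rejected_times_s < hi)
        ],
    )


def _burg_recursion(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg lattice recursion.

    Returns the denominator coefficients a_1..a_p (convention
    A(z) = 1 + sum a_k z^-k) and the final prediction-error power.
    """
    n = x.size
    a = np.ones(1)
    energy = float(x @ x) / n  # epsilon_0
    ef = x.copy()
    eb = x.copy()
    for _ in range(order):
        efp = ef[1:]
        ebp = eb[:-1]
        den = float(efp @ efp + ebp @ ebp)
        if den <= 0:
            break  # prediction error exhausted; remaining coefficients zero
        k = -2.0 * float(efp @ ebp) / den
        ef = efp + k * ebp
        eb = ebp + k * efp
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        energy *= 1.0 - k * k
    if a.size < order + 1:
        a = np.concatenate([a, np.zeros(order + 1 - a.size)])
    return a[1:], energy


def fit_burg(x: UniformTachogram, order: int = 16) -> ARModel:
    """Fit an AR model to the mean-removed tachogram by Burg's method."""
    if order < 0:
        raise ValidationError("order must be >= 0")
    data = x.values_ms - np.mean(x.values_ms)
    if order > 0 and data.size <= 2 * order:
        raise ValidationError(
            f"tachogram length {data.size} must exceed twice the order {order}"
        )
    if np.allclose(data, 0.0):
        raise ValidationError("zero-variance tachogram cannot be modelled")
    coeffs, epsilon = _burg_recursion(data, order)
    model = ARModel(order=order, coefficients=coeffs, epsilon=epsilon, fs=x.rate_hz)
    logger.info("fit_burg: order %d, epsilon %.4g ms^2", order, epsilon)
    return model


def psd_burg(m: ARModel, n_freqs: int = 4096) -> SpectralEstimate:
    """One-sided AR PSD on a uniform grid over [0, fs/2].

    The default grid is deliberately fine: high-order AR spectra of strongly
    periodic tachograms have very narrow peaks whose band-integral mass a
    coarse grid visibly underestimates.
    """
    if n_freqs < 2:
        raise ValidationError("need at least 2 frequency points")
    freqs = np.linspace(0.0, m.fs / 2.0, n_freqs)
    # A(e^{-j 2 pi f / fs}) = 1 + sum_k a_k e^{-2 pi j k f / fs}
    k = np.arange(1, m.order + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / m.fs)
    denom = np.abs(1.0 + phase @ m.coefficients.astype(complex)) ** 2
    psd = (m.epsilon / m.fs) / denom
    # one-sided: double everything strictly between DC and Nyquist
    psd = psd * 2.0
    psd[0] /= 2.0
    psd[-1] /= 2.0
    return SpectralEstimate(freqs_hz=freqs, psd=psd, method="burg", order=m.order)


def psd_welch(
    x: UniformTachogram, window_s: float = 150.0, overlap_frac: float = 0.5
) -> SpectralEstimate:
    """Welch averaged modified periodogram (Hann window, one-sided density)."""
    nperseg = int(round(window_s * x.rate_hz))
    if nperseg > len(x):
        raise ValidationError(
            f"Welch window {window_s} s exceeds record length {x.duration_s} s"
        )
    if not 0 <= overlap_frac < 1:
        raise ValidationError("overlap fraction must be in [0, 1)")
    freqs, psd = signal.welch(
        x.values_ms,
        fs=x.rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap_frac),
        detrend="constant",
        scaling="density",
    )
    return SpectralEstimate(freqs_hz=freqs, psd=psd, method="welch")


def psd_wavelet(x: UniformTachogram) -> SpectralEstimate:
    """Global wavelet spectrum: time-averaged Morlet scalogram as a PSD.

    The scalogram's per-scale time average is mapped scale -> frequency and
    rescaled by one constant so the trapezoid integral over the analyzed
    band equals the series variance (the calibration making band integrals
    comparable to Welch's).
    """
    from .time_frequency import cwt_scalogram

    if len(x) < 64:
        raise ValidationError("record too short for wavelet spectrum (need >= 64 samples)")
    variance = float(np.var(x.values_ms))
    f_max = x.rate_hz / 2.0
    scal = cwt_scalogram(x, f_min=0.003, f_max=f_max)
    gws = scal.power.mean(axis=0)  # average over time
    freqs = scal.freqs_hz
    if variance == 0.0:
        return SpectralEstimate(freqs_hz=freqs, psd=np.zeros_like(gws), method="wavelet")
    area = float(np.trapezoid(gws, freqs))
    psd = gws * (variance / area) if area > 0 else gws
    return SpectralEstimate(freqs_hz=freqs, psd=psd, method="wavelet")


def _band_integral(s: SpectralEstimate, low: float, high: float) -> float:
    """Trapezoid integral of the PSD over [low, high], interpolating the edges."""
    f, p = s.freqs_hz, s.psd
    low = max(low, float(f[0]))
    high = min(high, float(f[-1]))
    if high <= low:
        return 0.0
    inner = (f > low) & (f < high)
    grid = np.concatenate(([low], f[inner], [high]))
    vals = np.interp(grid, f, p)
    return float(np.trapezoid(vals, grid))


def band_powers(
    s: SpectralEstimate,
    cfg: AnalysisConfig | None = None,
    record_duration_s: float = 300.0,
) -> FrequencyDomainIndices:
    """Integrate the PSD over the configured ULF/VLF/LF/HF bands.

    ULF is only reported for recordings of at least one hour.  Total power is
    the integral over [0, HF upper edge].  When HF power vanishes the ratio
    and normalized units are reported absent with a warning.
    """
    cfg = cfg or AnalysisConfig()
    edges = cfg.band_edges
    if s.freqs_hz[-1] < edges["hf"][1] - 1e-9:
        raise ValidationError(
            f"spectrum reaches only {s.freqs_hz[-1]} Hz; bands need {edges['hf'][1]} Hz"
        )
    ulf = _band_integral(s, *edges["ulf"])
    vlf = _band_integral(s, *edges["vlf"])
    lf = _band_integral(s, *edges["lf"])
    hf = _band_integral(s, *edges["hf"])
    tp = _band_integral(s, 0.0, edges["hf"][1])
    lf_nu = hf_nu = ratio = None
    if lf + hf > 0:
        lf_nu = lf / (lf + hf)
        hf_nu = hf / (lf + hf)
    if hf > 0:
        ratio = lf / hf
    else:
        warnings.warn("HF power is zero; LF/HF ratio not reported", stacklevel=2)
    return FrequencyDomainIndices(
        total_power_ms2=tp,
        ulf_ms2=ulf if record_duration_s >= 3600.0 else None,
        vlf_ms2=vlf,
        lf_ms2=lf,
        hf_ms2=hf,
        lf_nu=lf_nu,
        hf_nu=hf_nu,
        lf_hf_ratio=ratio,
    )


def analyze_frequency_domain(
    x: UniformTachogram,
    cfg: AnalysisConfig | None = None,
    method: str = "burg",
) -> tuple[SpectralEstimate, FrequencyDomainIndices]:
    """Convenience wrapper: estimate the PSD and integrate the bands."""
    cfg = cfg or AnalysisConfig()
    if method == "burg":
        est = psd_burg(fit_burg(x, cfg.burg_order))
    elif method == "welch":
        est = psd_welch(x, window_s=min(150.0, x.duration_s / 2.0))
    elif method == "wavelet":
        est = psd_wavelet(x)
    else:
        raise ValidationError(f"unknown spectral method {method!r}")
    return est, band_powers(est, cfg, record_duration_s=x.duration_s)
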