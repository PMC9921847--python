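"""Time-frequency HRV analysis.

Two complementary views of how spectral power moves over a recording:

* a windowed Burg periodogram — per sliding window, fit an AR model and
  integrate the band powers, yielding the LF/HF sympathovagal-balance
  dynamics and the full time x frequency power surface;
* a continuous wavelet transform scalogram (analytic Morlet, omega0 = 6)
  with log-spaced scales and a marked cone of influence.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt

from .config import AnalysisConfig
from .datatypes import BalanceDynamics, SpectroTemporalMap, UniformTachogram
from .errors import ConfigurationError, ValidationError
from .frequency_domain import band_powers, fit_burg, psd_burg

logger = logging.getLogger("cardiokit")

# complex Morlet with envelope exp(-t^2/2) and centre frequency omega0=6
# (pywt's cmorB-C has envelope exp(-t^2/B) and centre C cycles per unit time)
_MORLET = "cmor2.0-0.9549"
_HF_FLOOR_MS2 = 1e-6  # windows with less HF power emit no LF/HF point


def _window_starts(n: int, win: int, step: int) -> list[int]:
    return list(range(0, n - win + 1, step))


def windowed_band_dynamics(
    x: UniformTachogram,
    cfg: AnalysisConfig | None = None,
    window_s: float = 300.0,
    step_s: float = 60.0,
) -> BalanceDynamics:
    """LF/HF ratio per sliding Burg-spectrum window, centred on the window midpoint."""
    cfg = cfg or AnalysisConfig()
    win = int(round(window_s * x.rate_hz))
    step = max(1, int(round(step_s * x.rate_hz)))
    if win > len(x):
        raise ValidationError(
            f"record ({x.duration_s:.0f} s) shorter than one window ({window_s:.0f} s)"
        )
    times: list[float] = []
    ratios: list[float] = []
    for start in _window_starts(len(x), win, step):
        chunk = UniformTachogram(
            values_ms=x.values_ms[start : start + win],
            rate_hz=x.rate_hz,
            start_time_s=x.start_time_s + start / x.rate_hz,
        )
        if np.allclose(chunk.values_ms, chunk.values_ms[0]):
            continue
        est = psd_burg(fit_burg(chunk, cfg.burg_order))
        idx = band_powers(est, cfg, record_duration_s=window_s)
        if idx.hf_ms2 < _HF_FLOOR_MS2 or idx.lf_hf_ratio is None:
            continue
        times.append(chunk.start_time_s + window_s / 2.0)
        ratios.append(idx.lf_hf_ratio)
    logger.info("windowed_band_dynamics: %d windows emitted", len(times))
    return BalanceDynamics(
        times_s=np.asarray(times),
        lf_hf=np.asarray(ratios),
        window_s=window_s,
        step_s=step_s,
    )


def spectral_surface(
    x: UniformTachogram,
    cfg: AnalysisConfig | None = None,
    window_s: float = 300.0,
    step_s: float = 60.0,
    n_freqs: int = 256,
) -> SpectroTemporalMap:
    """Matrix of per-window Burg PSDs (time x frequency).

    Each row is exactly the PSD of that window analyzed alone; windows with
    zero variance contribute an all-zero row.
    """
    cfg = cfg or AnalysisConfig()
    win = int(round(window_s * x.rate_hz))
    step = max(1, int(round(step_s * x.rate_hz)))
    if win > len(x):
        raise ValidationError(
            f"record ({x.duration_s:.0f} s) shorter than one window ({window_s:.0f} s)"
        )
    freqs = np.linspace(0.0, x.rate_hz / 2.0, n_freqs)
    rows: list[np.ndarray] = []
    times: list[float] = []
    for start in _window_starts(len(x), win, step):
        chunk_vals = x.values_ms[start : start + win]
        t_mid = x.start_time_s + start / x.rate_hz + window_s / 2.0
        if np.allclose(chunk_vals, chunk_vals[0]):
            rows.append(np.zeros(n_freqs))
        else:
            chunk = UniformTachogram(
                values_ms=chunk_vals, rate_hz=x.rate_hz, start_time_s=0.0
            )
            rows.append(psd_burg(fit_burg(chunk, cfg.burg_order), n_freqs).psd)
        times.append(t_mid)
    return SpectroTemporalMap(
        times_s=np.asarray(times),
        freqs_hz=freqs,
        power=np.vstack(rows) if rows else np.empty((0, n_freqs)),
        method="windowed_burg",
    )


def cwt_scalogram(
    x: UniformTachogram,
    f_min: float = 0.003,
    f_max: float = 0.5,
    n_voices: int = 64,
) -> SpectroTemporalMap:
    """Analytic Morlet scalogram with log-spaced scales and cone of influence.

    Power is the squared modulus of the wavelet coefficients; ``coi_mask`` is
    True where the time point lies inside the cone of influence (far enough
    from both record edges for that frequency's e-folding time).
    """
    if len(x) < 64:
        raise ValidationError("record too short for CWT (need >= 64 samples)")
    nyquist = x.rate_hz / 2.0
    if f_max > nyquist + 1e-12:
        raise ConfigurationError(f"f_max {f_max} Hz exceeds Nyquist {nyquist} Hz")
    if not 0 < f_min < f_max:
        raise ValidationError("need 0 < f_min < f_max")
    dt = 1.0 / x.rate_hz
    freqs = np.geomspace(f_min, f_max, n_voices)
    centre = pywt.central_frequency(_MORLET)  # cycles per unit of the mother wavelet
    scales = centre / (freqs * dt)
    coefs, actual_freqs = pywt.cwt(
        x.values_ms - np.mean(x.values_ms), scales, _MORLET, sampling_period=dt
    )
    power = np.abs(coefs.T) ** 2  # (time, freq)
    # ascending frequency order
    order = np.argsort(actual_freqs)
    freqs_sorted = actual_freqs[order]
    power = power[:, order]
    # cone of influence: e-folding time sqrt(2)*s_tc, Fourier period 1.033*s_tc
    times_rel = np.arange(len(x)) * dt
    coi_time = np.sqrt(2.0) / (1.033 * freqs_sorted)  # seconds, per frequency
    span = times_rel[-1]
    coi_mask = (times_rel[:, None] >= coi_time[None, :]) & (
        (span - times_rel)[:, None] >= coi_time[None, :]
    )
    return SpectroTemporalMap(
        times_s=x.start_time_s + times_rel,
        freqs_hz=freqs_sorted,
        power=power,
        method="cwt",
        coi_mask=coi_mask,
    )


def export_map_csv(m: SpectroTemporalMap, prefix: str) -> None:
    """Write the power matrix plus its two axis files as CSV."""
    np.savetxt(f"{prefix}_power.csv", m.power, delimiter=",")
    np.savetxt(f"{prefix}_times_s.csv", m.times_s, delimiter=",")
    np.savetxt(f"{prefix}_freqs_hz.csv", m.freqs_hz, delimiter=",")
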