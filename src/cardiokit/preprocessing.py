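"""Waveform-to-tachogram preprocessing.

The chain is: denoise -> beat detection (R peaks for ECG, systolic maxima for
PPG) -> RR extraction -> normal-to-normal filtering -> cubic-spline
resampling onto a uniform (default 2 Hz) grid.

The R-peak detector is a Pan–Tompkins-style chain: zero-phase 5–15 Hz
band-pass, derivative, squaring, 150 ms moving-window integration, adaptive
dual thresholds, and refinement of each fiducial to the local raw-signal
maximum.  All thresholds are relative, so detection is invariant to positive
amplitude scaling.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .config import NNFilterParams
from .datatypes import BeatSeries, NNSeries, RRSeries, UniformTachogram, WaveformRecord
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger("cardiokit")

# denoising band edges per modality, Hz: (stop_lo, pass_lo, pass_hi, stop_hi);
# below stop_lo and above stop_hi the gain is exactly zero, with raised-cosine
# transitions in between
_DENOISE_BAND = {"ECG": (0.5, 1.0, 35.0, 40.0), "PPG": (0.5, 0.9, 8.0, 10.0)}


def _fft_bandpass(
    x: np.ndarray, fs: float, stop_lo: float, pass_lo: float, pass_hi: float, stop_hi: float
) -> np.ndarray:
    """Zero-phase frequency-domain band-pass with raised-cosine transitions.

    Exactly zero phase (no peak-time shift) and free of the edge ringing an
    IIR filtfilt leaves on short records.
    """
    n = x.size
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.ones_like(freqs)
    gain[freqs <= stop_lo] = 0.0
    rise = (freqs > stop_lo) & (freqs < pass_lo)
    gain[rise] = 0.5 * (1 - np.cos(np.pi * (freqs[rise] - stop_lo) / (pass_lo - stop_lo)))
    gain[freqs >= stop_hi] = 0.0
    fall = (freqs > pass_hi) & (freqs < stop_hi)
    gain[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - pass_hi) / (stop_hi - pass_hi)))
    return np.fft.irfft(np.fft.rfft(x) * gain, n=n)


def denoise(w: WaveformRecord) -> WaveformRecord:
    """Zero-phase band-pass removing baseline wander and high-frequency noise."""
    if w.duration_s < 2.0:
        raise ValidationError("waveform shorter than 2 s")
    stop_lo, pass_lo, pass_hi, stop_hi = _DENOISE_BAND[w.modality]
    if w.sampling_rate_hz < 2.0 * stop_hi:
        raise ConfigurationError(
            f"sampling rate {w.sampling_rate_hz} Hz below twice the "
            f"{stop_hi} Hz upper passband edge"
        )
    filtered = _fft_bandpass(w.samples, w.sampling_rate_hz, stop_lo, pass_lo, pass_hi, stop_hi)
    return WaveformRecord(
        samples=filtered, sampling_rate_hz=w.sampling_rate_hz, modality=w.modality
    )


def _bandpass(x: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    sos = signal.butter(3, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _adaptive_peaks(
    feature: np.ndarray,
    fs: float,
    refractory_s: float,
    threshold_fraction: float = 0.25,
) -> np.ndarray:
    """Adaptive dual-threshold peak picking on a non-negative feature signal.

    Running signal/noise peak estimates (SPK/NPK) set the detection threshold
    NPK + fraction*(SPK - NPK), updated exponentially as each candidate is
    classified.  Entirely relative: scaling the feature leaves output unchanged.
    """
    min_distance = max(1, int(round(refractory_s * fs)))
    candidates, _ = signal.find_peaks(feature, distance=min_distance)
    if candidates.size == 0:
        return candidates
    # initial estimates from the first two seconds (or the whole record)
    head = feature[: max(int(2 * fs), 1)]
    spk = float(np.max(head))
    npk = float(np.mean(head)) * 0.5
    if spk <= 0:
        return np.empty(0, dtype=int)
    accepted: list[int] = []
    for idx in candidates:
        value = feature[idx]
        threshold = npk + threshold_fraction * (spk - npk)
        if value > threshold:
            if accepted and idx - accepted[-1] < min_distance:
                # keep the larger of two conflicting detections
                if value > feature[accepted[-1]]:
                    accepted[-1] = idx
                continue
            accepted.append(int(idx))
            spk = 0.125 * value + 0.875 * spk
        else:
            npk = 0.125 * value + 0.875 * npk
    return np.asarray(accepted, dtype=int)


def _refine_to_local_max(
    raw: np.ndarray, indices: np.ndarray, fs: float, half_window_s: float
) -> np.ndarray:
    half = max(1, int(round(half_window_s * fs)))
    refined = []
    for idx in indices:
        lo = max(0, idx - half)
        hi = min(raw.size, idx + half + 1)
        refined.append(lo + int(np.argmax(raw[lo:hi])))
    out = np.unique(np.asarray(refined, dtype=int))
    return out


def detect_r_peaks(w: WaveformRecord) -> BeatSeries:
    """Locate R peaks in a single-lead ECG (Pan–Tompkins-style)."""
    if w.modality != "ECG":
        raise ValidationError("detect_r_peaks expects an ECG record")
    if w.sampling_rate_hz < 100:
        raise ConfigurationError("ECG detection needs sampling rate >= 100 Hz")
    if w.duration_s < 5:
        raise ValidationError("ECG record shorter than 5 s")
    fs = w.sampling_rate_hz
    if np.ptp(w.samples) == 0:
        return BeatSeries(beat_times_s=np.empty(0))
    band = _bandpass(w.samples, fs, 5.0, 15.0)
    deriv = np.gradient(band)
    squared = deriv**2
    mwi = np.convolve(
        squared, np.ones(max(1, int(round(0.150 * fs)))) / max(1, int(round(0.150 * fs))),
        mode="same",
    )
    peaks = _adaptive_peaks(mwi, fs, refractory_s=0.200)
    if peaks.size == 0:
        return BeatSeries(beat_times_s=np.empty(0))
    # refine onto the filtered ECG (baseline-free) local maximum within +/-50 ms
    base = _bandpass(w.samples, fs, 0.5, min(40.0, 0.45 * fs))
    refined = _refine_to_local_max(base, peaks, fs, half_window_s=0.050)
    refined = _enforce_refractory(base, refined, int(round(0.200 * fs)))
    times = refined / fs
    logger.info("detect_r_peaks: %d beats in %.1f s", times.size, w.duration_s)
    return BeatSeries(beat_times_s=times)


def detect_ppg_peaks(w: WaveformRecord) -> BeatSeries:
    """Locate systolic maxima (P points) in a PPG pulse waveform."""
    if w.modality != "PPG":
        raise ValidationError("detect_ppg_peaks expects a PPG record")
    if w.sampling_rate_hz < 25:
        raise ConfigurationError("PPG detection needs sampling rate >= 25 Hz")
    fs = w.sampling_rate_hz
    if np.ptp(w.samples) == 0:
        return BeatSeries(beat_times_s=np.empty(0))
    band = _bandpass(w.samples, fs, 0.5, min(8.0, 0.45 * fs))
    feature = np.clip(band, 0.0, None) ** 2
    peaks = _adaptive_peaks(feature, fs, refractory_s=0.300)
    if peaks.size == 0:
        return BeatSeries(beat_times_s=np.empty(0))
    refined = _refine_to_local_max(band, peaks, fs, half_window_s=0.150)
    refined = _enforce_refractory(band, refined, int(round(0.300 * fs)))
    times = refined / fs
    logger.info("detect_ppg_peaks: %d beats in %.1f s", times.size, w.duration_s)
    return BeatSeries(beat_times_s=times)


def _enforce_refractory(raw: np.ndarray, indices: np.ndarray, min_gap: int) -> np.ndarray:
    """Drop the smaller of any two detections closer than the refractory period."""
    if indices.size < 2:
        return indices
    kept = [int(indices[0])]
    for idx in indices[1:]:
        if idx - kept[-1] < min_gap:
            if raw[idx] > raw[kept[-1]]:
                kept[-1] = int(idx)
        else:
            kept.append(int(idx))
    return np.asarray(kept, dtype=int)


def extract_rr(beats: BeatSeries) -> RRSeries:
    """Differences of adjacent beat times, in ms.

    An interval is labeled abnormal when either of its endpoint beats is.
    Series built from interval files carry a virtual origin beat, so all n
    intervals are recovered.
    """
    times = beats.beat_times_s
    labels = list(beats.labels)
    if beats.origin_time_s is not None:
        times = np.concatenate(([beats.origin_time_s], times))
        labels = ["normal"] + labels
    if times.size < 2:
        raise ValidationError("need at least 2 beats to form RR intervals")
    intervals = np.diff(times) * 1000.0
    pair_labels = [
        labels[i] if labels[i] != "normal" else labels[i + 1]
        for i in range(len(labels) - 1)
    ]
    return RRSeries(intervals_ms=intervals, end_times_s=times[1:], labels=pair_labels)


def filter_to_nn(rr: RRSeries, params: NNFilterParams | None = None) -> NNSeries:
    """Keep only normal-to-normal intervals.

    Rejects intervals that (a) touch a non-normal beat, (b) fall outside the
    physiologic bounds, or (c) deviate more than ``tolerance`` from the
    running median of the last ``median_window`` accepted intervals.  A
    rejection splits the series into segments; intervals across a gap are
    never differenced downstream.
    """
    params = params or NNFilterParams()
    if len(rr) < 2:
        raise ValidationError("need at least 2 RR intervals")
    intervals = rr.intervals_ms
    in_bounds = (intervals >= params.min_ms) & (intervals <= params.max_ms)
    # seed the running median from the leading in-bound intervals
    seed_pool = intervals[in_bounds][: params.median_window]
    accepted_idx: list[int] = []
    accepted_vals: list[float] = []
    rejected_idx: list[int] = []
    for i, value in enumerate(intervals):
        if rr.labels[i] != "normal" or not in_bounds[i]:
            rejected_idx.append(i)
            continue
        window = accepted_vals[-params.median_window :]
        ref = float(np.median(window)) if window else (
            float(np.median(seed_pool)) if seed_pool.size else value
        )
        if abs(value - ref) > params.tolerance * ref:
            rejected_idx.append(i)
            continue
        accepted_idx.append(i)
        accepted_vals.append(float(value))
    if not accepted_idx:
        raise ValidationError("no normal intervals")
    accepted = np.asarray(accepted_idx, dtype=int)
    # segment ids: a new segment starts wherever accepted indices are not adjacent
    segment_ids = np.zeros(accepted.size, dtype=int)
    if accepted.size > 1:
        segment_ids[1:] = np.cumsum(np.diff(accepted) != 1)
    nn = NNSeries(
        nn_intervals_ms=intervals[accepted],
        nn_end_times_s=rr.end_times_s[accepted],
        segment_ids=segment_ids,
        n_rejected=len(rejected_idx),
        rejected_times_s=rr.end_times_s[np.asarray(rejected_idx, dtype=int)]
        if rejected_idx
        else np.empty(0),
    )
    logger.info(
        "filter_to_nn: %d of %d intervals kept (%d rejected, %d segments)",
        len(nn),
        len(rr),
        nn.n_rejected,
        segment_ids.max() + 1 if segment_ids.size else 0,
    )
    return nn


def resample_tachogram(nn: NNSeries, rate_hz: float = 2.0) -> UniformTachogram:
    """Cubic-spline interpolation of the NN series onto a uniform grid.

    The spline passes through (interval end time, interval length) and is
    evaluated from the first to the last beat time only (no extrapolation).
    """
    if rate_hz <= 0:
        raise ValidationError("resample rate must be positive")
    if len(nn) < 4:
        raise ValidationError("need at least 4 NN intervals to resample")
    t = nn.nn_end_times_s
    if t[-1] - t[0] < 2.0:
        raise ValidationError("NN series spans less than 2 s")
    spline = CubicSpline(t, nn.nn_intervals_ms, bc_type="natural")
    n_grid = int(np.floor((t[-1] - t[0]) * rate_hz)) + 1
    grid = t[0] + np.arange(n_grid) / rate_hz
    values = spline(grid)
    logger.info("resample_tachogram: %d NN -> %d samples at %g Hz", len(nn), n_grid, rate_hz)
    return UniformTachogram(values_ms=values, rate_hz=rate_hz, start_time_s=float(t[0]))


def waveform_to_nn(
    w: WaveformRecord, params: NNFilterParams | None = None
) -> NNSeries:
    """Full preprocessing chain from a raw waveform to an NN series."""
    clean = denoise(w)
    beats = detect_r_peaks(clean) if w.modality == "ECG" else detect_ppg_peaks(clean)
    rr = extract_rr(beats)
    return filter_to_nn(rr, params)
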