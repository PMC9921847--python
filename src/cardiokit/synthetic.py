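"""Synthetic cardio-signal generators with known ground truth.

Every analysis stage is testable without clinical data:

* ``generate_rr`` builds a beat-by-beat RR series as a mean level plus
  sinusoidal LF/HF (optionally VLF) modulation tones and broadband Gaussian
  noise, with ectopic couplets (a 0.6x short interval followed by a 1.4x
  compensatory one) injected at a Poisson rate and labelled;
* ``generate_ecg`` / ``generate_ppg`` render a beat list into waveforms
  (Gaussian P-QRS-T templates with the R apex exactly on the beat time; a
  lognormal-like asymmetric pulse wave whose systolic peak sits a constant
  pulse-transit offset after the beat), so detector output can be scored
  against exact truth;
* ``generate_cohort`` draws per-subject generator parameters from presets
  that mirror the qualitative healthy / heart-failure-like /
  tachycardia-like contrasts (reduced variability and modulation in disease,
  shortest mean RR in tachycardia) without claiming clinical realism;
* ``generate_fgn`` (fractional Gaussian noise by circulant embedding) and
  ``generate_power_law_noise`` supply sequences of exactly known scaling
  exponent for the nonlinear estimators.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import BeatSeries, NNSeries, WaveformRecord
from .errors import ValidationError


@dataclass
class ToneSpec:
    freq_hz: float
    amplitude_ms: float

    def __post_init__(self) -> None:
        if not 0 < self.freq_hz < 0.5:
            raise ValidationError("tone frequency must be in (0, 0.5) Hz")
        if self.amplitude_ms < 0:
            raise ValidationError("tone amplitude must be >= 0")


@dataclass
class RRGenSpec:
    """Parameters of one synthetic RR series."""

    duration_s: float = 300.0
    mean_rr_ms: float = 800.0
    lf_tone: ToneSpec = field(default_factory=lambda: ToneSpec(0.10, 30.0))
    hf_tone: ToneSpec = field(default_factory=lambda: ToneSpec(0.25, 20.0))
    vlf_tone: ToneSpec | None = None
    broadband_sd_ms: float = 10.0
    ectopic_rate_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr_ms <= 0:
            raise ValidationError("mean RR must be positive")
        if self.broadband_sd_ms < 0 or self.ectopic_rate_per_min < 0:
            raise ValidationError("noise SD and ectopic rate must be >= 0")
        if self.duration_s <= 0:
            raise ValidationError("duration must be positive")


@dataclass
class SyntheticRR:
    """Generated RR series plus its ground truth."""

    intervals_ms: np.ndarray
    beat_times_s: np.ndarray  # beat i closes interval i; origin beat at t=0
    labels: list[str]
    spec: RRGenSpec

    def as_beat_series(self) -> BeatSeries:
        return BeatSeries(
            beat_times_s=self.beat_times_s, labels=list(self.labels), origin_time_s=0.0
        )

    def as_nn_series(self) -> NNSeries:
        """Ground-truth NN series: normal intervals, segments split at ectopics."""
        idx = np.flatnonzero(np.asarray(self.labels) == "normal")
        if idx.size == 0:
            raise ValidationError("no normal intervals in generated series")
        segment_ids = np.zeros(idx.size, dtype=int)
        if idx.size > 1:
            segment_ids[1:] = np.cumsum(np.diff(idx) != 1)
        return NNSeries(
            nn_intervals_ms=self.intervals_ms[idx],
            nn_end_times_s=self.beat_times_s[idx],
            segment_ids=segment_ids,
            n_rejected=len(self.labels) - idx.size,
            rejected_times_s=self.beat_times_s[
                np.asarray([i for i in range(len(self.labels)) if i not in set(idx)], dtype=int)
            ]
            if len(self.labels) > idx.size
            else np.empty(0),
        )


def generate_rr(spec: RRGenSpec) -> SyntheticRR:
    """Beat-by-beat RR construction: mean + modulation tones + Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    tones = [t for t in (spec.lf_tone, spec.hf_tone, spec.vlf_tone) if t is not None]
    intervals: list[float] = []
    t = 0.0
    while t < spec.duration_s:
        rr = spec.mean_rr_ms
        for tone in tones:
            rr += tone.amplitude_ms * np.sin(2.0 * np.pi * tone.freq_hz * t)
        if spec.broadband_sd_ms > 0:
            rr += rng.normal(0.0, spec.broadband_sd_ms)
        if rr <= 0:
            raise ValidationError(
                "generator parameters produced a non-positive RR interval"
            )
        intervals.append(rr)
        t += rr / 1000.0
    rr_ms = np.asarray(intervals)
    labels = ["normal"] * rr_ms.size

    if spec.ectopic_rate_per_min > 0 and rr_ms.size > 3:
        n_ectopic = rng.poisson(spec.ectopic_rate_per_min * spec.duration_s / 60.0)
        candidates = rng.permutation(rr_ms.size - 1)[:n_ectopic]
        for i in sorted(candidates):
            if labels[i] != "normal" or labels[i + 1] != "normal":
                continue
            rr_ms[i] *= 0.6  # premature beat
            rr_ms[i + 1] *= 1.4  # compensatory pause
            labels[i] = labels[i + 1] = "ectopic"
    beat_times = np.cumsum(rr_ms) / 1000.0
    return SyntheticRR(intervals_ms=rr_ms, beat_times_s=beat_times, labels=labels, spec=spec)


# --- waveform synthesis ---------------------------------------------------

# (time offset s, amplitude, Gaussian width s) of the P-QRS-T template waves
_ECG_WAVES = (
    (-0.200, 0.15, 0.025),  # P
    (-0.030, -0.15, 0.010),  # Q
    (0.000, 1.00, 0.010),  # R apex exactly on the beat
    (0.030, -0.20, 0.010),  # S
    (0.250, 0.35, 0.045),  # T
)


def generate_ecg(
    beats: BeatSeries, fs_hz: float = 250.0, snr_db: float | None = None, seed: int = 0
) -> WaveformRecord:
    """Template-based ECG: sums of Gaussians per beat plus optional white noise."""
    if fs_hz < 100:
        raise ValidationError("ECG synthesis needs fs >= 100 Hz")
    times = beats.beat_times_s
    if times.size == 0:
        raise ValidationError("no beats to synthesize")
    if times.size > 1 and np.min(np.diff(times)) < 0.250:
        raise ValidationError("beats closer than 250 ms are not synthesizable")
    t = np.arange(int(np.ceil((times[-1] + 0.5) * fs_hz))) / fs_hz
    ecg = np.zeros_like(t)
    for beat in times:
        lo = np.searchsorted(t, beat - 0.45)
        hi = np.searchsorted(t, beat + 0.55)
        seg = t[lo:hi] - beat
        for offset, amp, width in _ECG_WAVES:
            ecg[lo:hi] += amp * np.exp(-0.5 * ((seg - offset) / width) ** 2)
    if snr_db is not None and np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        noise_sd = float(np.sqrt(np.var(ecg) / 10.0 ** (snr_db / 10.0)))
        ecg = ecg + rng.normal(0.0, noise_sd, ecg.size)
    return WaveformRecord(samples=ecg, sampling_rate_hz=fs_hz, modality="ECG")


def generate_ppg(
    beats: BeatSeries,
    fs_hz: float = 50.0,
    seed: int = 0,
    transit_offset_s: float = 0.25,
) -> WaveformRecord:
    """Pulse-wave PPG: asymmetric (fast-rise, slow-decay) pulse per beat.

    The systolic peak sits exactly ``transit_offset_s`` after each beat, so
    PP intervals equal RR intervals regardless of the offset value.
    """
    if fs_hz < 25:
        raise ValidationError("PPG synthesis needs fs >= 25 Hz")
    times = beats.beat_times_s
    if times.size == 0:
        raise ValidationError("no beats to synthesize")
    if times.size > 1 and np.min(np.diff(times)) < 0.250:
        raise ValidationError("beats closer than 250 ms are not synthesizable")
    t = np.arange(int(np.ceil((times[-1] + transit_offset_s + 1.0) * fs_hz))) / fs_hz
    ppg = np.zeros_like(t)
    rise, decay = 0.09, 0.22
    for beat in times:
        peak = beat + transit_offset_s
        lo = np.searchsorted(t, peak - 0.4)
        hi = np.searchsorted(t, peak + 0.8)
        u = t[lo:hi] - peak
        width = np.where(u < 0, rise, decay)
        ppg[lo:hi] += np.exp(-0.5 * (u / width) ** 2)
    del seed  # waveform is deterministic; kept for interface symmetry
    return WaveformRecord(samples=ppg, sampling_rate_hz=fs_hz, modality="PPG")


# --- cohorts --------------------------------------------------------------


@dataclass
class CohortPreset:
    """Per-subject parameter distributions (mean, sd) for a study-like group."""

    name: str
    mean_rr_ms: tuple[float, float]
    lf_amplitude_ms: tuple[float, float]
    hf_amplitude_ms: tuple[float, float]
    broadband_sd_ms: tuple[float, float]
    ectopic_rate_per_min: float = 0.0
    duration_s: float = 600.0


COHORT_PRESETS: dict[str, CohortPreset] = {
    # healthy: longest mean RR of the non-tachycardic groups, largest LF/HF
    # modulation and beat-to-beat variability
    "healthy": CohortPreset(
        name="healthy",
        mean_rr_ms=(850.0, 60.0),
        lf_amplitude_ms=(45.0, 8.0),
        hf_amplitude_ms=(32.0, 6.0),
        broadband_sd_ms=(22.0, 4.0),
        ectopic_rate_per_min=0.5,
    ),
    # heart-failure-like: globally depressed variability and modulation
    "heart_failure_like": CohortPreset(
        name="heart_failure_like",
        mean_rr_ms=(650.0, 50.0),
        lf_amplitude_ms=(14.0, 3.0),
        hf_amplitude_ms=(12.0, 3.0),
        broadband_sd_ms=(9.0, 2.0),
        ectopic_rate_per_min=2.0,
    ),
    # tachycardia-like: shortest RR (fastest rate), modest modulation
    "tachycardia_like": CohortPreset(
        name="tachycardia_like",
        mean_rr_ms=(550.0, 40.0),
        lf_amplitude_ms=(16.0, 4.0),
        hf_amplitude_ms=(15.0, 4.0),
        broadband_sd_ms=(10.0, 2.0),
        ectopic_rate_per_min=1.0,
    ),
}


def generate_cohort(
    preset: CohortPreset | str, n_subjects: int, seed: int = 0
) -> list[SyntheticRR]:
    """Draw per-subject RR generator specs from a preset and generate them."""
    if isinstance(preset, str):
        preset = COHORT_PRESETS[preset]
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    subjects: list[SyntheticRR] = []
    for i in range(n_subjects):
        spec = RRGenSpec(
            duration_s=preset.duration_s,
            mean_rr_ms=max(350.0, rng.normal(*preset.mean_rr_ms)),
            lf_tone=ToneSpec(0.10, max(0.0, rng.normal(*preset.lf_amplitude_ms))),
            hf_tone=ToneSpec(0.25, max(0.0, rng.normal(*preset.hf_amplitude_ms))),
            broadband_sd_ms=max(1.0, rng.normal(*preset.broadband_sd_ms)),
            ectopic_rate_per_min=preset.ectopic_rate_per_min,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(generate_rr(spec))
    return subjects


# --- reference noise for the scaling estimators ---------------------------


def generate_fgn(hurst: float, n: int, seed: int = 0) -> np.ndarray:
    """Fractional Gaussian noise of exponent H by circulant embedding.

    The autocovariance gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2 is
    embedded in a circulant matrix whose eigenvalues are computed by FFT;
    H = 0.5 reduces to white noise.
    """
    if not 0 < hurst < 1:
        raise ValidationError("Hurst exponent must be in (0, 1)")
    if n < 2:
        raise ValidationError("need n >= 2")
    rng = np.random.default_rng(seed)
    k = np.arange(n)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst)
    )
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    eigs = np.clip(np.fft.fft(circ).real, 0.0, None)  # tiny negatives from rounding
    m = circ.size
    z = rng.normal(size=m) + 1j * rng.normal(size=m)
    x = np.fft.fft(np.sqrt(eigs) * z).real[:n]
    return x / np.std(x)  # unit variance; scaling is irrelevant to H


def generate_power_law_noise(exponent: float, n: int, seed: int = 0) -> np.ndarray:
    """Gaussian noise with PSD proportional to 1/f^exponent (0 = white, 1 = pink)."""
    if n < 2:
        raise ValidationError("need n >= 2")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amplitude = np.zeros_like(freqs)
    amplitude[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    x = np.fft.irfft(amplitude * phases, n=n)
    return x / np.std(x)
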