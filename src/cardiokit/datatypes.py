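"""Core containers for the HRV pipeline.

The pipeline is waveform -> beats -> NN intervals -> uniform tachogram ->
indices.  Each stage has a small dataclass; arrays are numpy, times in
seconds, intervals in milliseconds (the unit every HRV index is quoted in).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ValidationError

Modality = Literal["ECG", "PPG"]
BeatLabel = Literal["normal", "ectopic", "artifact"]

LABEL_CODES = {"N": "normal", "E": "ectopic", "A": "artifact"}


@dataclass
class WaveformRecord:
    """Uniformly sampled single-channel physiological signal."""

    samples: np.ndarray
    sampling_rate_hz: float
    modality: Modality = "ECG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("waveform needs at least 2 samples in one channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("waveform contains non-finite samples")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.modality not in ("ECG", "PPG"):
            raise ValidationError(f"unknown modality {self.modality!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class BeatSeries:
    """Detected (or given) beat times with per-beat labels.

    ``origin_time_s`` records an implicit leading beat when the series was
    built from an interval list: interval i closes at ``beat_times_s[i]`` and
    the first interval opens at the origin.  Detector output has no origin.
    """

    beat_times_s: np.ndarray
    labels: list[str] = field(default_factory=list)
    origin_time_s: float | None = None

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.beat_times_s.size and np.any(np.diff(self.beat_times_s) <= 0):
            raise ValidationError("beat times must be strictly increasing")
        if not self.labels:
            self.labels = ["normal"] * self.beat_times_s.size
        if len(self.labels) != self.beat_times_s.size:
            raise ValidationError("labels and beat times differ in length")

    def __len__(self) -> int:
        return int(self.beat_times_s.size)


@dataclass
class RRSeries:
    """Unfiltered RR intervals (candidate NN series before normal-beat filtering).

    ``labels[i]`` is abnormal when either endpoint beat of interval i is.
    """

    intervals_ms: np.ndarray
    end_times_s: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.end_times_s = np.asarray(self.end_times_s, dtype=float)
        if self.intervals_ms.size != self.end_times_s.size:
            raise ValidationError("intervals and end times differ in length")
        if not self.labels:
            self.labels = ["normal"] * self.intervals_ms.size

    def __len__(self) -> int:
        return int(self.intervals_ms.size)


@dataclass
class NNSeries:
    """Normal-to-normal intervals after artifact/ectopic exclusion.

    Rejections never bridge: ``segment_ids`` marks maximal runs of intervals
    with no rejected beat in between, and successive-difference statistics
    (RMSSD, NN50) only pair intervals within one segment.
    """

    nn_intervals_ms: np.ndarray
    nn_end_times_s: np.ndarray
    segment_ids: np.ndarray | None = None
    n_rejected: int = 0
    rejected_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.nn_intervals_ms = np.asarray(self.nn_intervals_ms, dtype=float)
        self.nn_end_times_s = np.asarray(self.nn_end_times_s, dtype=float)
        self.rejected_times_s = np.asarray(self.rejected_times_s, dtype=float)
        if self.nn_intervals_ms.size != self.nn_end_times_s.size:
            raise ValidationError("intervals and end times differ in length")
        if self.nn_intervals_ms.size and np.any(self.nn_intervals_ms <= 0):
            raise ValidationError("NN intervals must be positive")
        if self.nn_end_times_s.size and np.any(np.diff(self.nn_end_times_s) <= 0):
            raise ValidationError("NN end times must be strictly increasing")
        if self.segment_ids is None:
            self.segment_ids = np.zeros(self.nn_intervals_ms.size, dtype=int)
        else:
            self.segment_ids = np.asarray(self.segment_ids, dtype=int)
        if self.segment_ids.size != self.nn_intervals_ms.size:
            raise ValidationError("segment ids and intervals differ in length")

    def __len__(self) -> int:
        return int(self.nn_intervals_ms.size)

    @property
    def start_time_s(self) -> float:
        """Clock time of the beat opening the first interval."""
        return float(self.nn_end_times_s[0] - self.nn_intervals_ms[0] / 1000.0)

    @property
    def duration_s(self) -> float:
        return float(self.nn_end_times_s[-1] - self.start_time_s)


@dataclass
class UniformTachogram:
    """NN series interpolated onto a uniform grid; input to all spectral methods."""

    values_ms: np.ndarray
    rate_hz: float = 2.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.values_ms = np.asarray(self.values_ms, dtype=float)
        if self.rate_hz <= 0:
            raise ValidationError("tachogram rate must be positive")
        if not np.all(np.isfinite(self.values_ms)):
            raise ValidationError("tachogram contains non-finite values")

    def __len__(self) -> int:
        return int(self.values_ms.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.values_ms.size) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.values_ms.size / self.rate_hz


@dataclass
class ARModel:
    """Autoregressive model in the convention A(z) = 1 + sum_k a_k z^-k."""

    order: int
    coefficients: np.ndarray  # a_1 .. a_p
    epsilon: float  # driving-noise (final prediction error) power, ms^2
    fs: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.order != self.coefficients.size:
            raise ValidationError("order does not match number of coefficients")
        if self.epsilon < 0:
            raise ValidationError("prediction error power must be non-negative")

    @property
    def poles(self) -> np.ndarray:
        """Roots of z^p + a_1 z^(p-1) + ... + a_p; stable iff all inside unit circle."""
        if self.order == 0:
            return np.empty(0, dtype=complex)
        return np.roots(np.concatenate(([1.0], self.coefficients)))


@dataclass
class SpectralEstimate:
    """One-sided PSD in ms^2/Hz on an ascending frequency grid."""

    freqs_hz: np.ndarray
    psd: np.ndarray
    method: str  # burg | welch | wavelet
    order: int | None = None

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs_hz.size != self.psd.size:
            raise ValidationError("frequency grid and PSD differ in length")
        if self.freqs_hz.size and np.any(np.diff(self.freqs_hz) <= 0):
            raise ValidationError("frequency grid must be strictly ascending")
        if np.any(self.psd < -1e-12):
            raise ValidationError("PSD must be non-negative")
        self.psd = np.clip(self.psd, 0.0, None)


@dataclass
class SpectroTemporalMap:
    """Time-frequency power matrix, shape (n_times, n_freqs), ms^2/Hz."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray
    method: str  # windowed_burg | cwt
    coi_mask: np.ndarray | None = None  # True where inside the cone of influence

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.times_s.size, self.freqs_hz.size):
            raise ValidationError("power matrix shape does not match grids")
        if np.any(self.power < -1e-12):
            raise ValidationError("power must be non-negative")
        self.power = np.clip(self.power, 0.0, None)


@dataclass
class BalanceDynamics:
    """LF/HF sympathovagal-balance ratio over sliding windows."""

    times_s: np.ndarray
    lf_hf: np.ndarray
    window_s: float
    step_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.lf_hf = np.asarray(self.lf_hf, dtype=float)
        if self.times_s.size != self.lf_hf.size:
            raise ValidationError("times and values differ in length")


@dataclass
class TimeDomainIndices:
    hr_min_bpm: float
    hr_max_bpm: float
    mean_hr_bpm: float
    mean_rr_ms: float
    sdnn_ms: float
    rmssd_ms: float
    nn50: int
    pnn50_pct: float
    sdann_ms: float | None = None
    sdindex_ms: float | None = None
    hrvti: float | None = None
    tinn_ms: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "HRmin": self.hr_min_bpm,
            "HRmax": self.hr_max_bpm,
            "MeanHR": self.mean_hr_bpm,
            "MeanRR": self.mean_rr_ms,
            "SDNN": self.sdnn_ms,
            "SDANN": self.sdann_ms,
            "RMSSD": self.rmssd_ms,
            "NN50": float(self.nn50),
            "pNN50": self.pnn50_pct,
            "SDindex": self.sdindex_ms,
            "HRVti": self.hrvti,
            "TINN": self.tinn_ms,
        }


@dataclass
class NNHistogram:
    """Histogram of NN intervals on uniform bins aligned to multiples of the width."""

    bin_edges_ms: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges_ms = np.asarray(self.bin_edges_ms, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.bin_edges_ms.size != self.counts.size + 1:
            raise ValidationError("need one more edge than counts")
        widths = np.diff(self.bin_edges_ms)
        if widths.size and not np.allclose(widths, widths[0]):
            raise ValidationError("bins must have uniform width")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])

    @property
    def centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


@dataclass
class FrequencyDomainIndices:
    total_power_ms2: float
    vlf_ms2: float
    lf_ms2: float
    hf_ms2: float
    ulf_ms2: float | None = None  # only for recordings >= 1 h
    lf_nu: float | None = None  # fractions in [0, 1]
    hf_nu: float | None = None
    lf_hf_ratio: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "TP": self.total_power_ms2,
            "ULF": self.ulf_ms2,
            "VLF": self.vlf_ms2,
            "LF": self.lf_ms2,
            "HF": self.hf_ms2,
            "LFnu": self.lf_nu,
            "HFnu": self.hf_nu,
            "LF/HF": self.lf_hf_ratio,
        }


@dataclass
class FitDiagnostics:
    """Log-log regression behind a scaling exponent."""

    log_scale: np.ndarray
    log_statistic: np.ndarray
    slope: float
    intercept: float
    r_squared: float


@dataclass
class NonlinearIndices:
    hurst: float | None = None
    alpha: float | None = None
    alpha1: float | None = None
    alpha2: float | None = None
    fit_points: dict[str, FitDiagnostics] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "Hurst": self.hurst,
            "Alpha": self.alpha,
            "Alpha1": self.alpha1,
            "Alpha2": self.alpha2,
        }


@dataclass
class Flag:
    parameter: str
    value: float
    low: float | None
    high: float | None
    status: str  # in_range | low | high | no_reference
    units: str = ""


@dataclass
class HRVReport:
    """Assembled indices plus out-of-range flags against reference ranges."""

    time_domain: TimeDomainIndices | None = None
    frequency_domain: FrequencyDomainIndices | None = None
    nonlinear: NonlinearIndices | None = None
    flags: list[Flag] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def index_values(self) -> dict[str, float]:
        """All computed (non-None) index values keyed by standard parameter name."""
        out: dict[str, float] = {}
        for block in (self.time_domain, self.frequency_domain, self.nonlinear):
            if block is not None:
                for name, value in block.as_dict().items():
                    if value is not None:
                        out[name] = float(value)
        return out
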