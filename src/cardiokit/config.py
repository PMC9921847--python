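"""Analysis configuration: frequency bands, model order, filtering rules, references.

Defaults follow the 1996 HRV Task Force conventions: ULF 0–0.003 Hz,
VLF 0.003–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.4 Hz; 2 Hz tachogram
resampling; 5-minute analysis segments; AR model order 16 (16–20 is the
recommended range for 2–4 Hz cardiac tachograms).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

DEFAULT_BAND_EDGES: dict[str, tuple[float, float]] = {
    "ulf": (0.0, 0.003),
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}


@dataclass
class ReferenceRange:
    """Healthy reference interval for one HRV parameter.

    ``low``/``high`` may each be absent (one-sided or missing reference).
    """

    parameter: str
    low: float | None = None
    high: float | None = None
    mean: float | None = None
    sd: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ConfigurationError(
                f"reference for {self.parameter}: low {self.low} > high {self.high}"
            )

    @property
    def has_bounds(self) -> bool:
        return self.low is not None or self.high is not None


@dataclass
class NNFilterParams:
    """Rules deciding which RR intervals count as normal-to-normal."""

    tolerance: float = 0.20  # max fractional deviation from the running median
    min_ms: float = 300.0  # physiologic bounds
    max_ms: float = 2000.0
    median_window: int = 11  # number of nearest accepted intervals in the running median

    def __post_init__(self) -> None:
        if not 0 < self.tolerance < 1:
            raise ConfigurationError("NN tolerance must be in (0, 1)")
        if self.min_ms <= 0 or self.max_ms <= self.min_ms:
            raise ConfigurationError("need 0 < min_ms < max_ms")
        if self.median_window < 1:
            raise ConfigurationError("median window must be >= 1")


@dataclass
class AnalysisConfig:
    band_edges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_EDGES)
    )
    burg_order: int = 16
    resample_rate_hz: float = 2.0
    segment_length_s: float = 300.0
    nn_filter_params: NNFilterParams = field(default_factory=NNFilterParams)
    histogram_bin_width_ms: float = 7.8125  # 1/128 s, the conventional HRV bin
    reference_table: list[ReferenceRange] = field(default_factory=list)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.burg_order < 1:
            raise ConfigurationError("burg_order must be >= 1")
        if self.resample_rate_hz <= 0:
            raise ConfigurationError("resample_rate_hz must be positive")
        if self.segment_length_s <= 0:
            raise ConfigurationError("segment_length_s must be positive")
        if self.histogram_bin_width_ms <= 0:
            raise ConfigurationError("histogram bin width must be positive")
        self._validate_bands()
        if not self.reference_table:
            self.reference_table = load_default_reference_table()

    def _validate_bands(self) -> None:
        nyquist = self.resample_rate_hz / 2.0
        prev_high = None
        for name in sorted(self.band_edges, key=lambda k: self.band_edges[k][0]):
            low, high = self.band_edges[name]
            if not (0 <= low < high <= nyquist):
                raise ConfigurationError(
                    f"band {name} ({low}-{high} Hz) outside [0, {nyquist}] Hz or inverted"
                )
            if prev_high is not None and low < prev_high:
                raise ConfigurationError(f"band {name} overlaps the previous band")
            prev_high = high

    def reference_for(self, parameter: str) -> ReferenceRange | None:
        for ref in self.reference_table:
            if ref.parameter == parameter:
                return ref
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat key-value config file; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must be a mapping")
        kwargs: dict = {}
        nn_kwargs: dict = {}
        band_edges = dict(DEFAULT_BAND_EDGES)
        valid = {f.name for f in dataclasses.fields(cls)}
        nn_valid = {f.name for f in dataclasses.fields(NNFilterParams)}
        for key, value in raw.items():
            if key in ("ulf", "vlf", "lf", "hf"):
                band_edges[key] = (float(value[0]), float(value[1]))
            elif key.startswith("nn_") and key[3:] in nn_valid:
                nn_kwargs[key[3:]] = value
            elif key in valid:
                kwargs[key] = value
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        kwargs["band_edges"] = band_edges
        if nn_kwargs:
            kwargs["nn_filter_params"] = NNFilterParams(**nn_kwargs)
        return cls(**kwargs)


def load_default_reference_table() -> list[ReferenceRange]:
    """Packaged healthy reference ranges (HRV standard values)."""
    import csv
    from importlib import resources

    table: list[ReferenceRange] = []
    ref_file = resources.files("cardiokit").joinpath("data/reference_ranges.csv")
    with ref_file.open() as fh:
        for row in csv.DictReader(fh):
            table.append(
                ReferenceRange(
                    parameter=row["parameter"],
                    mean=float(row["mean"]) if row["mean"] else None,
                    sd=float(row["sd"]) if row["sd"] else None,
                    low=float(row["low"]) if row["low"] else None,
                    high=float(row["high"]) if row["high"] else None,
                    units=row["units"],
                )
            )
    return table
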