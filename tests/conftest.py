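"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cardiokit.datatypes import NNSeries


def make_nn(values_ms, start_s: float = 0.0) -> NNSeries:
    """NN series from an interval list, beats at cumulative sums."""
    values = np.asarray(values_ms, dtype=float)
    return NNSeries(
        nn_intervals_ms=values, nn_end_times_s=start_s + np.cumsum(values) / 1000.0
    )


def naive_time_domain(values_ms) -> dict[str, float]:
    """Direct-formula time-domain statistics in plain Python (oracle).

    Independent of the package: explicit loops, no numpy vectorization.
    """
    x = [float(v) for v in values_ms]
    n = len(x)
    mean_rr = sum(x) / n
    sdnn = math.sqrt(sum((v - mean_rr) ** 2 for v in x) / (n - 1))
    hr = [60000.0 / v for v in x]
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs)) if diffs else 0.0
    nn50 = sum(1 for d in diffs if abs(d) > 50.0)
    pnn50 = 100.0 * nn50 / len(diffs) if diffs else 0.0
    return {
        "mean_rr_ms": mean_rr,
        "sdnn_ms": sdnn,
        "rmssd_ms": rmssd,
        "nn50": nn50,
        "pnn50_pct": pnn50,
        "hr_min_bpm": min(hr),
        "hr_max_bpm": max(hr),
        "mean_hr_bpm": sum(hr) / n,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
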