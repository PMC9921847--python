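"""Time-domain HRV indices.

Statistical indices (MeanRR, SDNN, SDANN, SDindex, RMSSD, NN50, pNN50 and the
instantaneous heart-rate extremes) plus the geometric histogram indices
(HRV triangular index, TINN).  Conventions:

* sample (N-1) standard deviations throughout;
* NN50 counts successive differences strictly greater than 50 ms;
* successive differences are only taken inside contiguous NN segments, so a
  rejected beat never contributes a spurious difference;
* SDANN/SDindex use non-overlapping 5-minute windows by clock time and are
  reported absent for records shorter than two windows;
* instantaneous heart rate is 60000/NN_i bpm.
"""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .datatypes import NNHistogram, NNSeries, TimeDomainIndices
from .errors import ConfigurationError, ValidationError

MIN_BEATS_PER_SEGMENT = 10


def _successive_diffs(nn: NNSeries) -> np.ndarray:
    """Differences between adjacent NN intervals within the same segment."""
    diffs = np.diff(nn.nn_intervals_ms)
    same_segment = np.diff(nn.segment_ids) == 0
    return diffs[same_segment]


def compute_time_domain(nn: NNSeries, cfg: AnalysisConfig | None = None) -> TimeDomainIndices:
    cfg = cfg or AnalysisConfig()
    x = nn.nn_intervals_ms
    if x.size < 2:
        raise ValidationError("need at least 2 NN intervals")
    hr = 60000.0 / x
    diffs = _successive_diffs(nn)
    nn50 = int(np.sum(np.abs(diffs) > 50.0))
    n_pairs = diffs.size
    rmssd = float(np.sqrt(np.mean(diffs**2))) if n_pairs else 0.0
    pnn50 = 100.0 * nn50 / n_pairs if n_pairs else 0.0

    sdann = sdindex = None
    if nn.duration_s >= 2.0 * cfg.segment_length_s:
        segments = segment_means_sds(nn, cfg.segment_length_s)
        if segments:
            means = np.asarray([s[1] for s in segments])
            sds = np.asarray([s[2] for s in segments])
            sdann = float(np.std(means, ddof=1)) if means.size > 1 else 0.0
            sdindex = float(np.mean(sds))

    hist = compute_histogram(nn, cfg.histogram_bin_width_ms)
    hrvti, tinn = geometric_indices(hist)

    return TimeDomainIndices(
        hr_min_bpm=float(hr.min()),
        hr_max_bpm=float(hr.max()),
        mean_hr_bpm=float(hr.mean()),
        mean_rr_ms=float(x.mean()),
        sdnn_ms=float(np.std(x, ddof=1)),
        rmssd_ms=rmssd,
        nn50=nn50,
        pnn50_pct=pnn50,
        sdann_ms=sdann,
        sdindex_ms=sdindex,
        hrvti=hrvti,
        tinn_ms=tinn,
    )


def segment_means_sds(
    nn: NNSeries, segment_length_s: float = 300.0
) -> list[tuple[float, float, float, int]]:
    """Per-window (start_s, mean_ms, sd_ms, n_beats) over non-overlapping windows.

    Windows are laid out by clock time from the first beat; windows with
    fewer than 10 NN intervals are skipped.
    """
    if segment_length_s <= 0:
        raise ValidationError("segment length must be positive")
    if nn.duration_s < segment_length_s:
        return []
    t0 = nn.start_time_s
    out: list[tuple[float, float, float, int]] = []
    n_windows = int(np.floor(nn.duration_s / segment_length_s))
    for k in range(n_windows):
        lo = t0 + k * segment_length_s
        hi = lo + segment_length_s
        mask = (nn.nn_end_times_s >= lo) & (nn.nn_end_times_s < hi)
        vals = nn.nn_intervals_ms[mask]
        if vals.size < MIN_BEATS_PER_SEGMENT:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append((float(lo), float(vals.mean()), sd, int(vals.size)))
    return out


def compute_histogram(nn: NNSeries, bin_width_ms: float = 7.8125) -> NNHistogram:
    """NN histogram on bins aligned to multiples of the bin width from zero."""
    if bin_width_ms <= 0:
        raise ConfigurationError("histogram bin width must be positive")
    x = nn.nn_intervals_ms
    if x.size < 1:
        raise ValidationError("need at least one interval")
    first = int(np.floor(x.min() / bin_width_ms))
    last = int(np.floor(x.max() / bin_width_ms))
    edges = np.arange(first, last + 2) * bin_width_ms
    counts, _ = np.histogram(x, bins=edges)
    return NNHistogram(bin_edges_ms=edges, counts=counts)


def geometric_indices(h: NNHistogram) -> tuple[float, float]:
    """HRV triangular index and TINN from the NN histogram.

    HRVti = total count / modal bin count.  TINN = M - N for the triangle
    with apex fixed at the modal bin centre (height = modal count) and base
    endpoints N, M searched exhaustively over the histogram's bin edges on
    either side of the mode, minimizing the squared error to the bin counts
    (zero outside the triangle).  Ties on the modal bin break toward the bin
    whose centre is closer to the count-weighted mean.
    """
    counts = h.counts.astype(float)
    if counts.sum() <= 0:
        raise ValidationError("empty histogram")
    peak = counts.max()
    hrvti = float(counts.sum() / peak)

    centers = h.centers_ms
    mean_rr = float(np.average(centers, weights=counts))
    modal_candidates = np.flatnonzero(counts == peak)
    mode_idx = int(modal_candidates[np.argmin(np.abs(centers[modal_candidates] - mean_rr))])
    apex_x = centers[mode_idx]
    apex_y = peak

    edges = h.bin_edges_ms
    best = (np.inf, edges[mode_idx], edges[mode_idx + 1])
    for n_edge in edges[: mode_idx + 1]:
        for m_edge in edges[mode_idx + 1 :]:
            tri = np.zeros_like(counts)
            left = (centers >= n_edge) & (centers < apex_x)
            right = (centers > apex_x) & (centers <= m_edge)
            if apex_x > n_edge:
                tri[left] = apex_y * (centers[left] - n_edge) / (apex_x - n_edge)
            tri[mode_idx] = apex_y
            if m_edge > apex_x:
                tri[right] = apex_y * (m_edge - centers[right]) / (m_edge - apex_x)
            sse = float(np.sum((counts - tri) ** 2))
            if sse < best[0] - 1e-12:
                best = (sse, n_edge, m_edge)
    tinn = float(best[2] - best[1])
    return hrvti, tinn
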