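"""Assemble a full HRV report from an NN series.

Time-domain indices run on the whole record; frequency-domain indices on a
5-minute segment (the first window passing the <=10% rejection quality gate
unless a start is given); nonlinear indices on the whole NN event series.
Every computed index is then flagged against the healthy reference ranges.
"""

from __future__ import annotations

import logging

from .compare_reference import flag_against_reference
from .config import AnalysisConfig
from .datatypes import HRVReport, NNSeries
from .errors import QualityError, ValidationError
from .frequency_domain import analyze_frequency_domain, select_segment
from .nonlinear import compute_nonlinear
from .preprocessing import resample_tachogram
from .time_domain import compute_time_domain

logger = logging.getLogger("cardiokit")

ALL_DOMAINS = ("time", "frequency", "nonlinear")


def _first_clean_segment(nn: NNSeries, cfg: AnalysisConfig) -> NNSeries | None:
    """First 5-min window passing the rejection quality gate, else None."""
    start = nn.start_time_s
    while start + cfg.segment_length_s <= nn.nn_end_times_s[-1] + 1e-9:
        try:
            return select_segment(nn, start, cfg.segment_length_s)
        except QualityError:
            start += cfg.segment_length_s
        except ValidationError:
            return None
    return None


def assemble_report(
    nn: NNSeries,
    cfg: AnalysisConfig | None = None,
    domains: tuple[str, ...] = ALL_DOMAINS,
    segment_start_s: float | None = None,
    spectral_method: str = "burg",
    provenance: dict | None = None,
) -> HRVReport:
    cfg = cfg or AnalysisConfig()
    report = HRVReport(provenance=provenance or {})
    if "time" in domains:
        report.time_domain = compute_time_domain(nn, cfg)
    if "frequency" in domains or "timefreq" in domains:
        if segment_start_s is not None:
            segment = select_segment(nn, segment_start_s, cfg.segment_length_s)
        else:
            segment = _first_clean_segment(nn, cfg)
        if segment is not None and len(segment) >= 4:
            tachogram = resample_tachogram(segment, cfg.resample_rate_hz)
            _, report.frequency_domain = analyze_frequency_domain(
                tachogram, cfg, method=spectral_method
            )
            report.provenance["segment_start_s"] = float(segment.start_time_s)
        else:
            logger.info("assemble_report: no clean 5-min segment; frequency domain skipped")
    if "nonlinear" in domains:
        try:
            report.nonlinear = compute_nonlinear(nn.nn_intervals_ms)
        except ValidationError as exc:
            logger.info("assemble_report: nonlinear skipped (%s)", exc)
    report.flags = flag_against_reference(report.index_values(), cfg.reference_table)
    return report
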