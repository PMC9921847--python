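"""Readers and writers for RR files, waveform CSVs, and HRV reports."""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

from .datatypes import (
    LABEL_CODES,
    BeatSeries,
    Flag,
    FrequencyDomainIndices,
    HRVReport,
    NonlinearIndices,
    TimeDomainIndices,
    WaveformRecord,
)
from .errors import ParseError, ValidationError

logger = logging.getLogger("cardiokit")


def read_rr_file(path: str | Path, dialect: str = "plain_ms") -> BeatSeries:
    """Read an RR/NN interval file into a :class:`BeatSeries`.

    ``plain_ms``: one interval in milliseconds per line.  Beat i is placed at
    the cumulative sum of intervals 1..i (the interval closes at its beat);
    a virtual origin beat at t=0 is recorded on the series.

    ``csv_time_rr``: header ``time_s,rr_ms[,label]`` with explicit beat times;
    labels N/E/A map to normal/ectopic/artifact and default to normal.
    """
    path = Path(path)
    if dialect == "plain_ms":
        intervals: list[float] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    value = float(line)
                except ValueError:
                    raise ParseError(f"non-numeric RR interval {line!r}", line=lineno)
                if value <= 0:
                    raise ValidationError(
                        f"line {lineno}: non-positive RR interval {value} ms"
                    )
                intervals.append(value)
        if not intervals:
            raise ValidationError(f"{path}: no RR intervals found")
        times = np.cumsum(np.asarray(intervals)) / 1000.0
        series = BeatSeries(beat_times_s=times, origin_time_s=0.0)
    elif dialect == "csv_time_rr":
        times_list: list[float] = []
        labels: list[str] = []
        rr_list: list[float] = []
        with open(path) as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "time_s" not in reader.fieldnames:
                raise ParseError("expected header time_s,rr_ms[,label]", line=1)
            for lineno, row in enumerate(reader, start=2):
                try:
                    t = float(row["time_s"])
                    rr = float(row["rr_ms"])
                except (TypeError, ValueError):
                    raise ParseError("non-numeric time_s/rr_ms", line=lineno)
                if rr <= 0:
                    raise ValidationError(f"line {lineno}: non-positive RR {rr} ms")
                times_list.append(t)
                rr_list.append(rr)
                raw_label = (row.get("label") or "N").strip() or "N"
                labels.append(LABEL_CODES.get(raw_label, raw_label))
        if not times_list:
            raise ValidationError(f"{path}: no beats found")
        # each row's interval closes at its beat; the first opens one RR earlier
        series = BeatSeries(
            beat_times_s=np.asarray(times_list),
            labels=labels,
            origin_time_s=times_list[0] - rr_list[0] / 1000.0,
        )
    else:
        raise ValidationError(f"unknown RR dialect {dialect!r}")
    logger.info("read_rr_file: %s -> %d beats", path, len(series))
    return series


def read_waveform_csv(
    path: str | Path, sampling_rate_hz: float, modality: str = "ECG"
) -> WaveformRecord:
    """Read a single-column or ``t,amplitude`` CSV waveform.

    Two-column files must be uniformly sampled: any |Δt − 1/fs| exceeding 1%
    of the sample period is rejected.
    """
    path = Path(path)
    if sampling_rate_hz <= 0:
        raise ValidationError("sampling rate must be positive")
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if lineno == 1 and any(not _is_number(f) for f in fields):
                continue  # header line
            for f in fields:
                if not _is_number(f):
                    raise ParseError(f"non-numeric value {f!r}", line=lineno)
            rows.append(fields)
    if not rows:
        raise ValidationError(f"{path}: empty waveform file")
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise ParseError("inconsistent column count")
    data = np.asarray([[float(f) for f in r] for r in rows])
    if ncols == 1:
        samples = data[:, 0]
    elif ncols == 2:
        t, samples = data[:, 0], data[:, 1]
        dt = np.diff(t)
        period = 1.0 / sampling_rate_hz
        if dt.size and np.max(np.abs(dt - period)) > 0.01 * period:
            raise ValidationError(
                f"{path}: time column is not uniform at {sampling_rate_hz} Hz "
                f"(max jitter {np.max(np.abs(dt - period)):.3g} s)"
            )
    else:
        raise ParseError(f"expected 1 or 2 columns, got {ncols}")
    if np.any(np.isnan(samples)):
        raise ValidationError(f"{path}: NaN samples")
    record = WaveformRecord(samples=samples, sampling_rate_hz=sampling_rate_hz, modality=modality)
    logger.info(
        "read_waveform_csv: %s -> %d samples (%.1f s %s)",
        path,
        record.n_samples,
        record.duration_s,
        modality,
    )
    return record


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# --- report serialization -------------------------------------------------


def write_report(report: HRVReport, path: str | Path, format: str = "json") -> None:
    """Serialize a report; JSON round-trips all numeric fields exactly."""
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_report_to_dict(report), fh, indent=2)
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "value", "units", "ref_low", "ref_high", "status"])
            for flag in report.flags:
                writer.writerow(
                    [
                        flag.parameter,
                        repr(flag.value),
                        flag.units,
                        "" if flag.low is None else repr(flag.low),
                        "" if flag.high is None else repr(flag.high),
                        flag.status,
                    ]
                )
    else:
        raise ValidationError(f"unknown report format {format!r}")
    logger.info("write_report: %s (%s, %d flags)", path, format, len(report.flags))


def read_report(path: str | Path) -> HRVReport:
    with open(path) as fh:
        raw = json.load(fh)
    return _report_from_dict(raw)


def _report_to_dict(report: HRVReport) -> dict:
    def block(obj):
        if obj is None:
            return None
        d = {k: v for k, v in vars(obj).items() if not k.startswith("fit_points")}
        return d

    return {
        "time_domain": block(report.time_domain),
        "frequency_domain": block(report.frequency_domain),
        "nonlinear": block(report.nonlinear),
        "flags": [vars(f) for f in report.flags],
        "provenance": report.provenance,
    }


def _report_from_dict(raw: dict) -> HRVReport:
    td = raw.get("time_domain")
    fd = raw.get("frequency_domain")
    nl = raw.get("nonlinear")
    return HRVReport(
        time_domain=TimeDomainIndices(**td) if td else None,
        frequency_domain=FrequencyDomainIndices(**fd) if fd else None,
        nonlinear=NonlinearIndices(**nl) if nl else None,
        flags=[Flag(**f) for f in raw.get("flags", [])],
        provenance=raw.get("provenance", {}),
    )
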