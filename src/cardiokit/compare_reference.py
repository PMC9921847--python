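"""Reference-range flagging, cross-modality agreement, and group comparison.

* Flagging marks each computed index low/high/in range against the packaged
  healthy reference table (inclusive bounds); parameters without a reference
  are labelled explicitly.
* Agreement between two paired series (e.g. the same subjects' SDNN from ECG
  and from PPG) is quantified either as the raw sum of squared differences
  or as a percent RMS error relative to the first series' mean.
* Group differences use the classical one-way ANOVA F test at the 0.05
  significance level.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import ReferenceRange
from .datatypes import Flag
from .errors import ValidationError

logger = logging.getLogger("cardiokit")

SIGNIFICANCE_LEVEL = 0.05

# normalized-unit indices are stored as fractions but referenced in percent
_PERCENT_SCALED = {"LFnu", "HFnu"}


def flag_against_reference(
    indices: dict[str, float], refs: list[ReferenceRange]
) -> list[Flag]:
    """Status per parameter: low/high/in_range with inclusive bounds.

    ``indices`` maps standard parameter names to values (as produced by
    ``HRVReport.index_values``).  LFnu/HFnu fractions are compared on the
    percent scale their reference is quoted in.
    """
    by_name = {r.parameter: r for r in refs}
    flags: list[Flag] = []
    for name, value in indices.items():
        ref = by_name.get(name)
        display_value = value * 100.0 if name in _PERCENT_SCALED and value <= 1.0 else value
        if ref is None or not ref.has_bounds:
            flags.append(
                Flag(
                    parameter=name,
                    value=display_value,
                    low=None,
                    high=None,
                    status="no_reference",
                    units=ref.units if ref else "",
                )
            )
            continue
        if ref.low is not None and display_value < ref.low:
            status = "low"
        elif ref.high is not None and display_value > ref.high:
            status = "high"
        else:
            status = "in_range"
        flags.append(
            Flag(
                parameter=name,
                value=display_value,
                low=ref.low,
                high=ref.high,
                status=status,
                units=ref.units,
            )
        )
    return flags


def paired_mse(
    x: np.ndarray, y: np.ndarray, normalization: str = "rms_relative_pct"
) -> float:
    """Agreement between two paired series.

    ``none``: the raw sum of squared differences, sum_i (x_i - y_i)^2.
    ``rms_relative_pct``: 100 * sqrt(sum (x_i - y_i)^2 / N) / mean(x), the
    percent relative RMS error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired series must have equal length")
    if x.size < 1:
        raise ValidationError("need at least one pair")
    raw = float(np.sum((x - y) ** 2))
    if normalization == "none":
        return raw
    if normalization == "rms_relative_pct":
        mean_x = float(np.mean(x))
        if mean_x == 0:
            raise ValidationError("relative normalization undefined for zero-mean reference")
        return 100.0 * float(np.sqrt(raw / x.size)) / mean_x
    raise ValidationError(f"unknown normalization {normalization!r}")


def compare_modalities(
    groups: dict[str, pd.DataFrame], normalization: str = "rms_relative_pct"
) -> pd.DataFrame:
    """Per-parameter agreement table across modality groups.

    Each value of ``groups`` is a (subjects x parameters) frame of one
    modality's per-subject indices; all frames must share subjects and
    parameters.  The output has one row per parameter and one column per
    modality pair, each cell the paired error over subjects.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two modality groups")
    names = list(groups)
    first = groups[names[0]]
    for name in names[1:]:
        frame = groups[name]
        if not frame.index.equals(first.index):
            raise ValidationError(f"group {name} has mismatched subjects")
        if list(frame.columns) != list(first.columns):
            raise ValidationError(f"group {name} has mismatched parameters")
    table = pd.DataFrame(index=first.columns, dtype=float)
    for a, b in itertools.combinations(names, 2):
        col = f"{a}-{b}"
        table[col] = [
            paired_mse(groups[a][p].to_numpy(), groups[b][p].to_numpy(), normalization)
            for p in first.columns
        ]
    table.index.name = "parameter"
    return table


def one_way_anova(*groups: np.ndarray) -> tuple[float, float, bool]:
    """Classical one-way ANOVA: (F statistic, p-value, significant at 0.05).

    Zero within-group variance with a nonzero between-group spread yields an
    infinite F; p is reported as 0 with a warning.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs at least 2 values")
    if sum(a.size for a in arrays) < 3:
        raise ValidationError("need at least 3 values in total")
    grand = np.concatenate(arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    if ss_within == 0 and ss_between > 0:
        warnings.warn("zero within-group variance; F is infinite, p reported as 0",
                      stacklevel=2)
        return float("inf"), 0.0, True
    f_stat, p_value = stats.f_oneway(*arrays)
    return float(f_stat), float(p_value), bool(p_value <= SIGNIFICANCE_LEVEL)
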