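"""Nonlinear HRV indices: rescaled-range Hurst exponent and DFA.

Both estimators work on the event-series NN intervals (not the resampled
tachogram, whose interpolation would inject spurious short-range
correlation) and reduce to the slope of a log-log regression:

* R/S — per window size n, partition the series into ``floor(N/n)`` blocks;
  in each block take the range R of the cumulative mean-adjusted sum and the
  sample SD S; H is the slope of log(mean R/S) against log n.
* DFA — integrate the mean-centred series, split into boxes of size n,
  linearly detrend each box, and let F(n) be the RMS residual; alpha1 is the
  slope over short scales (4-16 beats), alpha2 over long scales (16-64),
  alpha over their union.  Boxes are tiled from both ends of the series
  (standard two-pass variant) so trailing samples are not discarded.

Interpretation anchors: alpha (or H) of 0.5 means an uncorrelated series,
0.5-1 persistent fractal correlations, 1.0 is 1/f noise, 1.5 Brownian.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import FitDiagnostics, NonlinearIndices
from .errors import ValidationError

logger = logging.getLogger("cardiokit")


def _loglog_fit(scales: np.ndarray, stats: np.ndarray) -> FitDiagnostics:
    log_n = np.log10(scales)
    log_s = np.log10(stats)
    if log_n.size < 3:
        raise ValidationError("need at least 3 scales for a slope fit")
    slope, intercept = np.polyfit(log_n, log_s, 1)
    pred = slope * log_n + intercept
    ss_res = float(np.sum((log_s - pred) ** 2))
    ss_tot = float(np.sum((log_s - log_s.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitDiagnostics(
        log_scale=log_n,
        log_statistic=log_s,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
    )


def _log_spaced_ints(lo: int, hi: int, n: int) -> np.ndarray:
    vals = np.unique(np.round(np.geomspace(lo, hi, n)).astype(int))
    return vals[(vals >= lo) & (vals <= hi)]


def hurst_rs(x: np.ndarray) -> tuple[float, FitDiagnostics]:
    """Hurst exponent via the rescaled adjusted range statistic."""
    x = np.asarray(x, dtype=float)
    n_total = x.size
    if n_total < 256:
        raise ValidationError("need at least 256 samples for R/S analysis")
    if np.ptp(x) == 0:
        raise ValidationError("constant series has zero dispersion (S = 0)")
    sizes = _log_spaced_ints(16, n_total // 4, 12)
    if sizes.size < 8:
        sizes = _log_spaced_ints(16, n_total // 4, 16)
    rs_means: list[float] = []
    used_sizes: list[int] = []
    for n in sizes:
        n_blocks = n_total // n
        ratios: list[float] = []
        for b in range(n_blocks):
            block = x[b * n : (b + 1) * n]
            s = np.std(block, ddof=1)
            if s == 0:
                continue
            dev = np.cumsum(block - block.mean())
            r = float(dev.max() - dev.min())
            ratios.append(r / s)
        if ratios:
            rs_means.append(float(np.mean(ratios)))
            used_sizes.append(int(n))
    diag = _loglog_fit(np.asarray(used_sizes), np.asarray(rs_means))
    logger.info("hurst_rs: H=%.3f over %d window sizes (R^2=%.3f)",
                diag.slope, len(used_sizes), diag.r_squared)
    return diag.slope, diag


def _dfa_fluctuation(profile: np.ndarray, n: int) -> float:
    """RMS of linear-detrend residuals over boxes tiled from both series ends."""
    total = profile.size
    n_boxes = total // n
    t = np.arange(n, dtype=float)
    design = np.vstack([t, np.ones(n)]).T
    sq_sum = 0.0
    count = 0
    for segment_source in (profile[: n_boxes * n], profile[total - n_boxes * n :]):
        boxes = segment_source.reshape(n_boxes, n)
        coef, *_ = np.linalg.lstsq(design, boxes.T, rcond=None)
        resid = boxes.T - design @ coef
        sq_sum += float(np.sum(resid**2))
        count += n_boxes * n
    return float(np.sqrt(sq_sum / count))


def dfa(
    x: np.ndarray,
    scales1: tuple[int, int] = (4, 16),
    scales2: tuple[int, int] = (16, 64),
) -> tuple[float, float, float, dict[str, FitDiagnostics]]:
    """Detrended fluctuation analysis: overall alpha plus alpha1/alpha2."""
    x = np.asarray(x, dtype=float)
    max_scale = scales2[1]
    if x.size < 4 * max_scale:
        raise ValidationError(f"need at least {4 * max_scale} samples for DFA")
    if np.ptp(x) == 0:
        raise ValidationError("constant series has no fluctuations")
    profile = np.cumsum(x - x.mean())
    all_scales = np.unique(
        np.concatenate(
            [
                _log_spaced_ints(scales1[0], scales1[1], 8),
                _log_spaced_ints(scales2[0], scales2[1], 10),
            ]
        )
    )
    fluct = np.asarray([_dfa_fluctuation(profile, int(n)) for n in all_scales])
    keep = fluct > 0
    all_scales, fluct = all_scales[keep], fluct[keep]

    def sub(lo: int, hi: int) -> FitDiagnostics:
        mask = (all_scales >= lo) & (all_scales <= hi)
        return _loglog_fit(all_scales[mask], fluct[mask])

    diag_all = _loglog_fit(all_scales, fluct)
    diag1 = sub(*scales1)
    diag2 = sub(*scales2)
    logger.info(
        "dfa: alpha=%.3f alpha1=%.3f alpha2=%.3f", diag_all.slope, diag1.slope, diag2.slope
    )
    return (
        diag_all.slope,
        diag1.slope,
        diag2.slope,
        {"alpha": diag_all, "alpha1": diag1, "alpha2": diag2},
    )


def compute_nonlinear(x: np.ndarray) -> NonlinearIndices:
    """Hurst (R/S) plus DFA slopes for one NN interval sequence."""
    hurst, h_diag = hurst_rs(x)
    alpha, alpha1, alpha2, d_diags = dfa(x)
    fits = {"hurst_rs": h_diag}
    fits.update(d_diags)
    return NonlinearIndices(
        hurst=hurst, alpha=alpha, alpha1=alpha1, alpha2=alpha2, fit_points=fits
    )
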