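"""Time-series analysis of traction force dynamics.

After adhesion stabilizes, the max traction force of an implanting embryo
fluctuates with quasi-periodic peaks (~10-min recurrence) that precede
bursts of embryo displacement.  This module detects those peaks, computes
inter-peak interval statistics, associates peaks with subsequent
displacement, correlates local F-actin fluorescence with traction
strength, and compares force levels before/after inhibitor treatment.

A note on sampling: 10-min periodicity sampled at 5-min intervals sits at
the Nyquist limit; interval statistics are computed regardless, but a
warning is emitted whenever the mean interval is below three sampling
intervals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal, stats

from .series import TimeSeries, Trajectory

__all__ = [
    "PeakStats",
    "CorrelationResult",
    "PrePostSummary",
    "detect_peaks",
    "peak_displacement_association",
    "roi_correlation",
    "pre_post_compare",
]


@dataclass
class PeakStats:
    """Detected peaks and inter-peak interval statistics."""

    peak_times: np.ndarray     # min
    peak_heights: np.ndarray   # series unit

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_heights = np.asarray(self.peak_heights, dtype=float)

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.peak_times)

    @property
    def interval_mean(self) -> float:
        iv = self.intervals
        return float(iv.mean()) if iv.size else np.nan

    @property
    def interval_sd(self) -> float:
        iv = self.intervals
        return float(iv.std(ddof=1)) if iv.size > 1 else np.nan

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)


@dataclass
class CorrelationResult:
    """Least-squares line and Pearson r between paired measurements."""

    slope: float
    intercept: float
    r: float
    n: int
    p_value: float = np.nan
    flagged: bool = False
    reason: str = ""


@dataclass
class PrePostSummary:
    pre_mean: float
    post_mean: float
    ratio: float                       # post / pre
    half_decline_time: Optional[float]  # min after treatment, None if never


def detect_peaks(
    series: TimeSeries,
    prominence: Optional[float] = None,
    min_separation: Optional[float] = None,
) -> PeakStats:
    """Detect local maxima with prominence and separation thresholds.

    ``prominence`` defaults to 20% of the series interquartile range;
    ``min_separation`` (min) defaults to one sampling interval.  Plateau
    ties resolve to the earliest sample.  A series with no qualifying
    maxima yields empty PeakStats.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 samples")
    values = series.values
    dt = series.sampling_interval
    if prominence is None:
        q75, q25 = np.percentile(values, [75, 25])
        prominence = 0.2 * (q75 - q25)
    if prominence <= 0:
        prominence = None  # flat series: rely on strict local maxima
    distance = 1
    if min_separation is not None:
        distance = max(int(round(min_separation / dt)), 1)
    idx, props = signal.find_peaks(
        values, prominence=prominence, distance=distance,
        plateau_size=(1, None),
    )
    # plateau ties -> earliest sample
    if idx.size and "left_edges" in props:
        idx = props["left_edges"]
    stats_ = PeakStats(series.times[idx], values[idx])
    if stats_.n_peaks >= 2 and stats_.interval_mean < 3.0 * dt:
        warnings.warn(
            f"mean inter-peak interval ({stats_.interval_mean:.1f} min) is below "
            f"3x the sampling interval ({dt:.1f} min); interval statistics are "
            "near the Nyquist limit",
            stacklevel=2,
        )
    return stats_


def peak_displacement_association(
    peaks: PeakStats,
    trajectory: Trajectory,
    window: float = 5.0,
    threshold: Optional[float] = None,
) -> Tuple[float, pd.DataFrame]:
    """Fraction of force peaks followed by significant embryo displacement.

    For each peak at time t the embryo displacement within (t, t + window]
    is the maximum distance from the position at t; it counts as
    significant when it exceeds ``threshold`` (default: 2× the median
    per-interval step length of the trajectory).  Returns the fraction and
    a per-peak table.
    """
    if peaks.n_peaks == 0:
        return 0.0, pd.DataFrame(columns=["peak_time", "displacement", "associated"])
    t = trajectory.times
    span = t[-1] - t[0]
    if window > span:
        raise ValueError("window larger than the trajectory sampling span")
    if t[0] > peaks.peak_times.min() or t[-1] < peaks.peak_times.max():
        raise ValueError("trajectory must cover the peak time range")
    if threshold is None:
        steps = np.linalg.norm(trajectory.displacements, axis=1)
        threshold = 2.0 * float(np.median(steps))
    rows = []
    for tp in peaks.peak_times:
        at_peak = trajectory.positions[np.searchsorted(t, tp, side="right") - 1]
        in_window = (t > tp) & (t <= tp + window)
        if not in_window.any():
            disp = 0.0
        else:
            d = np.linalg.norm(trajectory.positions[in_window] - at_peak, axis=1)
            disp = float(d.max())
        rows.append((tp, disp, disp > threshold))
    table = pd.DataFrame(rows, columns=["peak_time", "displacement", "associated"])
    return float(table["associated"].mean()), table


def roi_correlation(
    mfi_values: np.ndarray,
    traction_values: np.ndarray,
) -> CorrelationResult:
    """Linear correlation between F-actin MFI and traction strength.

    Works for spatial pairings (several ROIs at one time point) and
    temporal pairings (one ROI followed over time) alike.  Zero variance
    in either variable leaves r undefined (flagged).
    """
    x = np.asarray(mfi_values, dtype=float)
    y = np.asarray(traction_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, x.size,
                                 flagged=True, reason="zero variance")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n=x.size,
        p_value=float(fit.pvalue),
    )


def pre_post_compare(series: TimeSeries, treatment_time: float) -> PrePostSummary:
    """Compare force levels before and after an inhibitor treatment.

    Returns segment means, their ratio, and the time after treatment at
    which the series first falls below half of the pre-treatment mean
    (None when it never does).
    """
    t = series.times
    pre = t < treatment_time
    post = t >= treatment_time
    if pre.sum() < 2 or post.sum() < 2:
        raise ValueError(
            "treatment_time must lie strictly inside the series with >= 2 "
            "samples on each side"
        )
    pre_mean = float(series.values[pre].mean())
    post_mean = float(series.values[post].mean())
    ratio = post_mean / pre_mean if pre_mean != 0 else np.nan
    below = post & (series.values < 0.5 * pre_mean)
    half_time = float(t[below][0] - treatment_time) if below.any() else None
    return PrePostSummary(pre_mean, post_mean, ratio, half_time)
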