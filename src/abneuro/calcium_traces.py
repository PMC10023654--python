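"""Twitch-2B ratio computation and per-cell spontaneous-activity features.

The ratiometric FRET indicator Twitch-2B reports intracellular calcium as the
ratio of background-corrected acceptor (cpVenus^CD) over donor (mCerulean3)
fluorescence.  This module turns a two-channel soma/background recording into
that ratio trace and extracts the features used to characterise spontaneous
activity: the basal ratio (mean of the lowest decile of samples), the maximum
ratio (peak 1.5 s sliding average), the time-normalised area under the curve,
and the number of mid-reference level crossings that feeds the fluctuation
classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "DualChannelTrace",
    "RatioTrace",
    "TraceFeatures",
    "compute_ratio",
    "lowpass_filter",
    "basal_ratio",
    "max_ratio",
    "auc_per_sec",
    "count_midcrossings",
    "state_levels",
    "extract_features",
    "read_trace_csv",
    "write_trace_csv",
]


@dataclass
class DualChannelTrace:
    """Soma and background fluorescence of both FRET channels for one cell.

    ``F_ven_*`` is the acceptor (cpVenus^CD) channel, ``F_cer_*`` the donor
    (mCerulean3) channel, all in arbitrary fluorescence units.
    """

    t: np.ndarray
    F_ven_soma: np.ndarray
    F_ven_bg: np.ndarray
    F_cer_soma: np.ndarray
    F_cer_bg: np.ndarray
    frame_rate_hz: float
    cell_id: str = ""
    mouse_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        arrs = [self.t, self.F_ven_soma, self.F_ven_bg, self.F_cer_soma, self.F_cer_bg]
        arrs = [np.asarray(a, dtype=float) for a in arrs]
        self.t, self.F_ven_soma, self.F_ven_bg, self.F_cer_soma, self.F_cer_bg = arrs
        n = len(self.t)
        if any(len(a) != n for a in arrs[1:]):
            raise ValueError("all channels must have the same length as t")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if not (1.0 <= self.frame_rate_hz <= 100.0):
            raise ValueError(f"frame_rate_hz {self.frame_rate_hz} outside [1, 100]")


@dataclass
class RatioTrace:
    """Dimensionless Twitch-2B ratio trace; ``filtered`` marks lowpass output."""

    t: np.ndarray
    ratio: np.ndarray
    frame_rate_hz: float
    filtered: bool = False
    cell_id: str = ""
    mouse_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if len(self.t) != len(self.ratio):
            raise ValueError("t and ratio must have equal length")
        if not np.all(np.isfinite(self.ratio)):
            raise ValueError("ratio trace contains non-finite values")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class TraceFeatures:
    """Per-cell spontaneous-activity summary."""

    cell_id: str
    basal_ratio: float
    max_ratio: float
    auc_per_sec: float
    n_crossings: int
    mouse_id: str = ""
    group: str = ""
    fluctuating: bool | None = None  # set by the clustering stage


def compute_ratio(trace: DualChannelTrace) -> RatioTrace:
    """Background-corrected acceptor/donor ratio.

    Ratio = (F_ven_soma - F_ven_bg) / (F_cer_soma - F_cer_bg), element-wise.
    A non-positive donor denominator signals a bad background ROI and raises
    with the offending sample index.
    """
    den = trace.F_cer_soma - trace.F_cer_bg
    bad = np.flatnonzero(den <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive donor denominator at sample index {bad[0]} "
            f"(value {den[bad[0]]:g}); check background ROI"
        )
    num = trace.F_ven_soma - trace.F_ven_bg
    return RatioTrace(
        t=trace.t,
        ratio=num / den,
        frame_rate_hz=trace.frame_rate_hz,
        filtered=False,
        cell_id=trace.cell_id,
        mouse_id=trace.mouse_id,
        group=trace.group,
    )


def lowpass_filter(rt: RatioTrace, cutoff_hz: float = 0.6, order: int = 4) -> RatioTrace:
    """Zero-phase lowpass Butterworth filter (default 0.6 Hz cut-off).

    Applied forward-backward (``filtfilt``) so the filter is zero phase with
    unit DC gain; the effective magnitude response is the squared one-pass
    Butterworth response.
    """
    nyq = rt.frame_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rt.frame_rate_hz, output="sos")
    filt = signal.sosfiltfilt(sos, rt.ratio)
    return RatioTrace(
        t=rt.t,
        ratio=filt,
        frame_rate_hz=rt.frame_rate_hz,
        filtered=True,
        cell_id=rt.cell_id,
        mouse_id=rt.mouse_id,
        group=rt.group,
    )


def basal_ratio(rt: RatioTrace) -> float:
    """Mean of the lowest 10% of sample values (count = ceil(0.1 N))."""
    n = len(rt.ratio)
    if n < 10:
        raise ValueError(f"trace too short for basal ratio ({n} < 10 samples)")
    k = int(np.ceil(0.1 * n))
    lowest = np.partition(rt.ratio, k - 1)[:k]
    return float(lowest.mean())


def max_ratio(rt: RatioTrace, window_s: float = 1.5) -> float:
    """Maximum of the sliding window mean (window 1.5 s, full windows only)."""
    w = int(round(window_s * rt.frame_rate_hz))
    w = max(w, 1)
    if w > len(rt.ratio):
        raise ValueError(
            f"trace shorter ({len(rt.ratio)} samples) than window ({w} samples)"
        )
    # cumulative-sum moving average over all full windows
    c = np.concatenate(([0.0], np.cumsum(rt.ratio)))
    means = (c[w:] - c[:-w]) / w
    return float(means.max())


def auc_per_sec(rt: RatioTrace, baseline: float) -> float:
    """Trapezoidal area of (ratio - baseline) divided by total duration."""
    if not np.isfinite(baseline):
        raise ValueError("baseline must be finite")
    dur = rt.duration_s
    if dur <= 0:
        raise ValueError("zero-duration trace")
    area = np.trapezoid(rt.ratio - baseline, rt.t)
    return float(area / dur)


def state_levels(x: np.ndarray, n_bins: int = 100) -> tuple[float, float]:
    """Low/high state levels of a (nominally bimodal) signal.

    Histogram over the sample range; the lower state level is the centre of
    the most populated bin in the lower half of the bins, the upper level the
    most populated bin in the upper half.  Ties are broken toward the extremes
    (lowest bin in the lower half, highest in the upper half).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return float(lo), float(hi)
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    half = n_bins // 2
    low_counts = counts[:half]
    high_counts = counts[half:]
    low_idx = int(np.flatnonzero(low_counts == low_counts.max())[0])
    rel = np.flatnonzero(high_counts == high_counts.max())[-1]
    high_idx = half + int(rel)
    return float(centers[low_idx]), float(centers[high_idx])


def count_midcrossings(rt: RatioTrace) -> int:
    """Number of mid-reference level crossings of the trace.

    The mid-reference level is the midpoint of the two state levels estimated
    by the bimodal-histogram method; a crossing is a pair of consecutive
    samples strictly straddling that level.
    """
    x = rt.ratio
    if len(x) < 2:
        raise ValueError("need at least 2 samples to count crossings")
    low, high = state_levels(x)
    if high == low:
        warnings.warn("constant trace: no state levels, 0 crossings", stacklevel=2)
        return 0
    mid = 0.5 * (low + high)
    s = x - mid
    return int(np.count_nonzero(s[:-1] * s[1:] < 0))


def extract_features(
    trace: DualChannelTrace,
    *,
    cutoff_hz: float = 0.6,
    filter_trace: bool = True,
    window_s: float = 1.5,
    auc_baseline: str = "basal",
) -> TraceFeatures:
    """Full feature pipeline for one cell.

    Ratio -> optional 0.6 Hz lowpass -> basal ratio, max ratio, AUC/s and
    mid-reference crossing count.  ``auc_baseline`` is ``"basal"`` (subtract
    the trace's own basal ratio) or ``"zero"``.
    """
    rt = compute_ratio(trace)
    if filter_trace:
        rt = lowpass_filter(rt, cutoff_hz=cutoff_hz)
    basal = basal_ratio(rt)
    if auc_baseline == "basal":
        base = basal
    elif auc_baseline == "zero":
        base = 0.0
    else:
        raise ValueError(f"unknown auc_baseline {auc_baseline!r}")
    return TraceFeatures(
        cell_id=trace.cell_id,
        mouse_id=trace.mouse_id,
        group=trace.group,
        basal_ratio=basal,
        max_ratio=max_ratio(rt, window_s=window_s),
        auc_per_sec=auc_per_sec(rt, base),
        n_crossings=count_midcrossings(rt),
    )


TRACE_COLUMNS = ["time_s", "cer_soma", "cer_bg", "ven_soma", "ven_bg"]


def read_trace_csv(
    path, frame_rate_hz: float | None = None, **ids
) -> DualChannelTrace:
    """Read a two-channel trace CSV (columns time_s, cer_soma, cer_bg,
    ven_soma, ven_bg).  The frame rate is inferred from the median sampling
    interval unless given."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if frame_rate_hz is None:
        frame_rate_hz = float(1.0 / np.median(np.diff(t)))
    return DualChannelTrace(
        t=t,
        F_ven_soma=df["ven_soma"].to_numpy(dtype=float),
        F_ven_bg=df["ven_bg"].to_numpy(dtype=float),
        F_cer_soma=df["cer_soma"].to_numpy(dtype=float),
        F_cer_bg=df["cer_bg"].to_numpy(dtype=float),
        frame_rate_hz=frame_rate_hz,
        **ids,
    )


def write_trace_csv(trace: DualChannelTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.t,
            "cer_soma": trace.F_cer_soma,
            "cer_bg": trace.F_cer_bg,
            "ven_soma": trace.F_ven_soma,
            "ven_bg": trace.F_ven_bg,
        }
    ).to_csv(path, index=False)
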