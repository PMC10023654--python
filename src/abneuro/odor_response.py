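"""Odor-evoked transient detection and responsiveness summaries.

Trials are expressed as relative ratio changes dR/R against a pre-stimulus
baseline, smoothed with a binomial (Pascal-row) filter, and screened with a
sharp-rise template-matching detector.  A trial responds when the best
candidate's amplitude exceeds three times the baseline noise SD (strictly);
the noise trace is raw dR/R minus its smoothed version.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .calcium_traces import RatioTrace

__all__ = [
    "OdorTrial",
    "TrialResult",
    "CellOdorSummary",
    "delta_r_over_r",
    "binomial_smooth",
    "make_template",
    "detect_response",
    "summarize_cell",
]


@dataclass
class OdorTrial:
    """One odor presentation: ratio trace plus stimulus window metadata."""

    t: np.ndarray
    ratio: np.ndarray
    frame_rate_hz: float
    stim_onset_s: float
    stim_dur_s: float = 4.0
    baseline_s: float = 5.0
    cell_id: str = ""
    mouse_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if len(self.t) != len(self.ratio):
            raise ValueError("t and ratio must have equal length")
        if not (self.t[0] <= self.stim_onset_s and self.stim_onset_s + self.stim_dur_s <= self.t[-1]):
            raise ValueError("stimulus window outside trace")
        if self.stim_onset_s - self.t[0] <= 0:
            raise ValueError("no pre-stimulus baseline available")

    @property
    def baseline_mask(self) -> np.ndarray:
        start = max(self.t[0], self.stim_onset_s - self.baseline_s)
        return (self.t >= start) & (self.t < self.stim_onset_s)


@dataclass
class TrialResult:
    drr: np.ndarray
    smoothed: np.ndarray
    noise_sd: float
    responded: bool
    amplitude: float | None
    auc: float | None
    peak_time_s: float | None = None


@dataclass
class CellOdorSummary:
    cell_id: str
    n_trials: int
    n_responded: int
    responsive: bool
    median_amplitude: float | None
    median_auc: float | None
    mouse_id: str = ""
    group: str = ""


def delta_r_over_r(trial: OdorTrial) -> np.ndarray:
    """(R - R0)/R0 with R0 the mean ratio over the pre-stimulus baseline."""
    r0 = float(trial.ratio[trial.baseline_mask].mean())
    if r0 <= 0:
        raise ValueError(f"non-positive baseline ratio R0={r0:g}")
    return (trial.ratio - r0) / r0


def binomial_smooth(x: np.ndarray, frame_rate_hz: float, window_s: float = 0.3) -> np.ndarray:
    """Smooth with a normalized binomial kernel spanning ~window_s.

    Kernel length round(window_s * frame_rate) forced odd (minimum 3); the
    weights are the corresponding Pascal-triangle row, so DC gain is exactly 1.
    Boundaries are handled by reflection.
    """
    x = np.asarray(x, dtype=float)
    n = int(round(window_s * frame_rate_hz))
    if n % 2 == 0:
        n += 1
    n = max(n, 3)
    if n > len(x):
        raise ValueError(f"kernel length {n} exceeds trace length {len(x)}")
    kernel = comb(n - 1, np.arange(n)) / 2.0 ** (n - 1)
    half = n // 2
    padded = np.pad(x, half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def make_template(
    frame_rate_hz: float, tau_rise_s: float = 0.2, tau_decay_s: float = 2.0
) -> np.ndarray:
    """Sharp-rise transient template: peak-normalized difference of
    exponentials sampled at the trial's frame rate (length 3 decay taus)."""
    if tau_decay_s <= tau_rise_s:
        raise ValueError("tau_decay must exceed tau_rise")
    t = np.arange(0.0, 3.0 * tau_decay_s, 1.0 / frame_rate_hz)
    y = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    return y / y.max()


def detect_response(
    trial: OdorTrial,
    *,
    threshold_sd: float = 3.0,
    response_margin_s: float = 2.0,
    tau_rise_s: float = 0.2,
    tau_decay_s: float = 2.0,
    strict: bool = True,
    min_correlation: float = 0.85,
) -> TrialResult:
    """Template-matching detection of an odor-evoked transient.

    The smoothed dR/R is cross-correlated (normalized) with the sharp-rise
    template over [onset, onset + stim + margin].  A window only qualifies as
    a candidate transient when its correlation reaches ``min_correlation``
    (the match criterion that makes this template matching rather than a bare
    peak search); the best candidate responds when its peak amplitude is
    > threshold_sd * noise SD (strict inequality unless ``strict=False``
    makes the boundary inclusive).
    """
    drr = delta_r_over_r(trial)
    smoothed = binomial_smooth(drr, trial.frame_rate_hz)
    noise = drr - smoothed
    noise_sd = float(noise[trial.baseline_mask].std(ddof=0))

    template = make_template(trial.frame_rate_hz, tau_rise_s, tau_decay_s)
    lo = float(trial.stim_onset_s)
    hi = float(trial.stim_onset_s + trial.stim_dur_s + response_margin_s)
    idx = np.flatnonzero((trial.t >= lo) & (trial.t <= hi))
    if idx.size == 0:
        raise ValueError("empty response search window")

    # normalized cross-correlation of template against windows starting in the
    # search range (windows truncated at the trace end)
    best_score, best_start = -np.inf, idx[0]
    tz = template - template.mean()
    tnorm = np.linalg.norm(tz)
    for start in idx:
        seg = smoothed[start : start + len(template)]
        if len(seg) < max(3, len(template) // 4):
            break
        tv = tz[: len(seg)]
        sv = seg - seg.mean()
        denom = np.linalg.norm(sv) * np.linalg.norm(tv)
        score = float(sv @ tv / denom) if denom > 0 else 0.0
        if score > best_score:
            best_score, best_start = score, int(start)

    if best_score < min_correlation:
        return TrialResult(
            drr=drr, smoothed=smoothed, noise_sd=noise_sd,
            responded=False, amplitude=None, auc=None,
        )

    extent = slice(best_start, min(best_start + len(template), len(smoothed)))
    seg = smoothed[extent]
    peak_rel = int(np.argmax(seg))
    amplitude = float(seg[peak_rel])

    if noise_sd == 0.0:
        warnings.warn("zero baseline noise SD: responding iff amplitude > 0", stacklevel=2)
        responded = amplitude > 0.0
    elif strict:
        responded = amplitude > threshold_sd * noise_sd
    else:
        responded = amplitude >= threshold_sd * noise_sd
    auc = float(np.trapezoid(seg, trial.t[extent])) if responded else None
    return TrialResult(
        drr=drr,
        smoothed=smoothed,
        noise_sd=noise_sd,
        responded=bool(responded),
        amplitude=amplitude if responded else None,
        auc=auc,
        peak_time_s=float(trial.t[extent][peak_rel]) if responded else None,
    )


def summarize_cell(
    cell_id: str,
    trials: list[TrialResult],
    rule: float = 0.5,
    mouse_id: str = "",
    group: str = "",
) -> CellOdorSummary:
    """Cell-level responsiveness: responded in >= ``rule`` fraction of trials.

    Amplitude and AUC are medians over the responding trials only.
    """
    if not trials:
        raise ValueError("need at least one trial")
    n_resp = sum(t.responded for t in trials)
    responsive = n_resp / len(trials) >= rule
    amps = [t.amplitude for t in trials if t.responded]
    aucs = [t.auc for t in trials if t.responded]
    return CellOdorSummary(
        cell_id=cell_id,
        n_trials=len(trials),
        n_responded=n_resp,
        responsive=bool(responsive),
        median_amplitude=float(np.median(amps)) if amps else None,
        median_auc=float(np.median(aucs)) if aucs else None,
        mouse_id=mouse_id,
        group=group,
    )
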