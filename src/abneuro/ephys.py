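"""Patch-clamp estimators: AP threshold, input resistance, resting potential.

The action-potential threshold is read from the first derivative of the
voltage trace: the membrane voltage at the first point inside the stimulus
window where dV/dt exceeds three standard deviations of its pre-stimulus
baseline, sustained for at least 0.2 ms (the sustain requirement rejects
single-sample noise crossings at 20 kHz).  Two cross-check modes are
provided: a fixed rate-of-rise criterion and the first peak of the third
derivative.  Input resistance comes from hyperpolarizing voltage steps via
Ohm's law; the resting membrane potential is the zero-current intercept of a
linear fit to the I-V table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoltageTrace",
    "IVTable",
    "ap_threshold",
    "input_resistance",
    "resting_potential",
]


@dataclass
class VoltageTrace:
    """Uniformly sampled current-clamp record (t in ms, V in mV)."""

    t_ms: np.ndarray
    v_mv: np.ndarray
    sampling_rate_hz: float
    stim_start_ms: float
    stim_end_ms: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.v_mv = np.asarray(self.v_mv, dtype=float)
        if len(self.t_ms) != len(self.v_mv):
            raise ValueError("t_ms and v_mv length mismatch")
        if self.stim_end_ms <= self.stim_start_ms:
            raise ValueError("invalid stimulus window")


@dataclass
class IVTable:
    """Holding potentials (mV) and steady-state holding currents (pA)."""

    v_mv: np.ndarray
    i_pa: np.ndarray

    def __post_init__(self) -> None:
        self.v_mv = np.asarray(self.v_mv, dtype=float)
        self.i_pa = np.asarray(self.i_pa, dtype=float)
        if len(self.v_mv) < 2:
            raise ValueError("need >= 2 I-V points")
        if len(np.unique(self.v_mv)) != len(self.v_mv):
            raise ValueError("holding potentials must be distinct")


def _dvdt(tr: VoltageTrace) -> np.ndarray:
    """Central-difference first derivative in mV/ms (== V/s)."""
    return np.gradient(tr.v_mv, tr.t_ms)


def ap_threshold(
    tr: VoltageTrace,
    *,
    baseline_ms: float = 100.0,
    sustain_ms: float = 0.2,
    mode: str = "dvdt_sd",
    sd_factor: float = 3.0,
    rate_of_rise_v_per_s: float = 50.0,
) -> float | None:
    """Action-potential threshold voltage, or None when no AP is detected.

    ``mode="dvdt_sd"`` (default): V at the first stimulus-window sample where
    dV/dt > sd_factor * SD(baseline dV/dt), sustained >= sustain_ms.
    ``mode="rate_of_rise"``: first sustained crossing of a fixed dV/dt level
    (default 50 V/s).  ``mode="third_derivative"``: V at the first local peak
    of d3V/dt3 inside the stimulus window.
    """
    if tr.stim_start_ms - tr.t_ms[0] < 50.0:
        raise ValueError("need >= 50 ms of pre-stimulus baseline")
    dv = _dvdt(tr)
    base_start = max(tr.t_ms[0], tr.stim_start_ms - baseline_ms)
    base = (tr.t_ms >= base_start) & (tr.t_ms < tr.stim_start_ms)
    stim = (tr.t_ms >= tr.stim_start_ms) & (tr.t_ms <= tr.stim_end_ms)
    stim_idx = np.flatnonzero(stim)
    if stim_idx.size == 0:
        raise ValueError("no samples inside stimulus window")

    if mode == "third_derivative":
        d3 = np.gradient(np.gradient(dv, tr.t_ms), tr.t_ms)
        seg = d3[stim_idx]
        peaks = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:])) + 1
        # require a nontrivial peak to avoid reporting baseline ripple
        peaks = peaks[seg[peaks] > 10.0 * np.abs(d3[base]).std()] if peaks.size else peaks
        if peaks.size == 0:
            return None
        return float(tr.v_mv[stim_idx[peaks[0]]])

    if mode == "dvdt_sd":
        sigma = float(dv[base].std(ddof=0))
        level = sd_factor * sigma
        if sigma == 0.0:
            level = 0.0  # noiseless record: any sustained depolarization counts
    elif mode == "rate_of_rise":
        level = rate_of_rise_v_per_s  # mV/ms == V/s
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n_sustain = max(1, int(round(sustain_ms * tr.sampling_rate_hz / 1000.0)))
    above = dv > level
    run = 0
    for i in stim_idx:
        if above[i]:
            run += 1
            if run >= n_sustain:
                first = i - n_sustain + 1
                return float(tr.v_mv[first])
        else:
            run = 0
    return None


def input_resistance(delta_v_mv, delta_i_pa) -> float:
    """Input resistance in megaohm from voltage steps and steady-state
    current responses, least squares through the origin (Ohm's law)."""
    dv = np.atleast_1d(np.asarray(delta_v_mv, dtype=float))
    di = np.atleast_1d(np.asarray(delta_i_pa, dtype=float))
    if len(dv) != len(di) or len(dv) < 1:
        raise ValueError("need matching, non-empty step arrays")
    denom = float(di @ di)
    if denom == 0.0:
        raise ValueError("zero current change: resistance undefined")
    slope_mv_per_pa = float(dv @ di) / denom
    return slope_mv_per_pa * 1e3  # mV/pA = GOhm -> MOhm


def resting_potential(iv: IVTable) -> float:
    """Resting membrane potential (mV): voltage at zero holding current from
    the least-squares line through the I-V points."""
    i, v = iv.i_pa, iv.v_mv
    if np.ptp(i) == 0:
        raise ValueError("all holding currents equal: I-V line undefined")
    slope, intercept = np.polyfit(i, v, 1)
    return float(intercept)
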