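"""Synthetic-data generators for every pipeline input, with ground truth.

Each generator emulates one class of study input at realistic desk scale —
two-channel FRET traces with double-exponential calcium events, saltatory 3-D
migration tracks, branching dendritic trees, two-session survival censuses,
negative-binomial count matrices with planted twofold expression changes,
odor trials, immunofluorescence FOV intensity sets, and current-clamp
records — and returns the data together with a ground-truth sidecar so the
downstream modules can be scored without the study's raw data.  All
generators are deterministic under a fixed seed.

Trace noise model: fluctuating cells carry double-exponential events on top
of the baseline; all cells carry white measurement noise plus a slow baseline
drift (amplitude tied to the noise level).  The slow component matters: the
mid-reference level of a drift-free pure-noise trace sits inside the noise
band, where the crossing rate of band-limited noise is amplitude-independent
and large, and the with/without-fluctuation crossing-count bimodality that
the classifier exploits would invert.  With the drift the mid level of a flat
cell is crossed only a handful of times, while an event cell's mid level sits
halfway up the event amplitude and is crossed about twice per transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium_traces import DualChannelTrace
from .migration import CellTrack
from .morphometry import NeuronTree
from .survival import DEFAULT_FOV_UM, DEFAULT_MARGIN_UM, FOVCensus
from .transcriptomics import CountMatrix
from .odor_response import OdorTrial
from .ephys import IVTable, VoltageTrace

__all__ = [
    "TraceSimSpec",
    "TrackSimSpec",
    "CountSimSpec",
    "TraceSimResult",
    "TrackSimResult",
    "TreeSimResult",
    "CensusSimResult",
    "CountSimResult",
    "gen_traces",
    "gen_tracks",
    "gen_trees",
    "gen_census_pair",
    "gen_counts",
    "gen_odor_trials",
    "gen_if_measurements",
    "gen_ap_trace",
    "gen_iv_table",
]


# --------------------------------------------------------------------------
# specs


@dataclass
class TraceSimSpec:
    """Study conditions for spontaneous-activity recordings: 2-min traces at
    a per-cell frame rate drawn uniformly in 7-10 Hz."""

    n_cells: int = 60
    frac_fluctuating: float = 0.575
    frame_rate_range_hz: tuple[float, float] = (7.0, 10.0)
    duration_s: float = 120.0
    baseline_ratio: float = 1.0
    event_rate_hz: float = 0.15
    event_amp: float = 0.5
    event_tau_rise_s: float = 0.5
    event_tau_decay_s: float = 2.0
    event_min_gap_s: float = 2.5  # refractory spacing: somatic transients do not stack unboundedly
    noise_sd: float = 0.005
    drift_factor: float = 10.0  # slow-drift amplitude as multiple of noise_sd
    n_mice: int = 8
    group: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_fluctuating <= 1.0:
            raise ValueError("frac_fluctuating must be in [0, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_rate_range_hz[0] <= 0:
            raise ValueError("frame rate must be positive")


@dataclass
class TrackSimSpec:
    """Saltatory pause/move trajectories: 17 positions over 4 h (15-min
    interval); migratory cells move in a random interval with probability
    p_move, by a step of mean step_scale_um."""

    n_cells: int = 50
    frac_migratory: float = 0.8
    p_move: float = 0.3
    step_scale_um: float = 8.0
    jitter_um: float = 0.5
    n_intervals: int = 16
    n_mice: int = 5
    group: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_um < 0:
            raise ValueError("jitter_um must be >= 0")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if not 0.0 <= self.frac_migratory <= 1.0:
            raise ValueError("frac_migratory must be in [0, 1]")


@dataclass
class CountSimSpec:
    """Negative-binomial count matrices with planted twofold-scale DEGs
    between a control and two channel-overexpression groups."""

    n_genes: int = 2000
    n_samples_per_group: int = 2
    groups: tuple[str, ...] = ("control", "kv", "kir")
    frac_de: float = 0.076
    log2fc_de: float = 2.0
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if self.log2fc_de < 0:
            raise ValueError("log2fc_de must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


# --------------------------------------------------------------------------
# results


@dataclass
class TraceSimResult:
    traces: list[DualChannelTrace]
    truth: pd.DataFrame  # cell_id, mouse_id, group, fluctuating, n_events, frame_rate_hz
    ratios: dict[str, np.ndarray]  # exact ground-truth ratio per cell


@dataclass
class TrackSimResult:
    tracks: list[CellTrack]
    truth: pd.DataFrame  # cell_id, mouse_id, group, migratory, n_move_intervals, path_um


@dataclass
class TreeSimResult:
    trees: list[NeuronTree]
    truth: pd.DataFrame  # tree index, tdbl_um, n_branches


@dataclass
class CensusSimResult:
    census_a: FOVCensus
    census_b: FOVCensus
    truth: pd.DataFrame  # cell_id, survived, newcomer


@dataclass
class CountSimResult:
    matrix: CountMatrix
    truth: pd.DataFrame  # gene, is_de, log2fc


# --------------------------------------------------------------------------
# trace generation


def _event_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Peak-normalized difference of exponentials (analytic peak, so a
    truncated tail near the end of a recording normalizes identically)."""
    y = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    t_peak = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return y / peak


def gen_traces(spec: TraceSimSpec) -> TraceSimResult:
    """Generate two-channel FRET traces with known fluctuation labels.

    The ratio trace is baseline + slow drift + events (fluctuating cells
    only) + white noise; the two fluorescence channels are derived from it so
    that the computed background-corrected acceptor/donor ratio reproduces it
    to machine precision, with the donor dipping during events as in a real
    FRET sensor.
    """
    if spec.duration_s <= 0 or spec.frame_rate_range_hz[0] <= 0:
        raise ValueError("non-positive duration or frame rate")
    rng = np.random.default_rng(spec.seed)
    n_fluct = int(round(spec.frac_fluctuating * spec.n_cells))
    fluct_idx = set(rng.choice(spec.n_cells, size=n_fluct, replace=False).tolist())
    mouse_of = rng.integers(0, spec.n_mice, size=spec.n_cells)

    traces: list[DualChannelTrace] = []
    ratios: dict[str, np.ndarray] = {}
    rows = []
    for i in range(spec.n_cells):
        fs = rng.uniform(*spec.frame_rate_range_hz)
        t = np.arange(0.0, spec.duration_s, 1.0 / fs)
        ratio = np.full_like(t, spec.baseline_ratio)

        # slow baseline drift (two incommensurate low-frequency components)
        if spec.noise_sd > 0 and spec.drift_factor > 0:
            amp = spec.drift_factor * spec.noise_sd
            for rel in (1.0, 0.5):
                period = rng.uniform(40.0, 120.0)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                ratio = ratio + rel * amp / 1.5 * np.sin(2 * np.pi * t / period + phase)

        is_fluct = i in fluct_idx
        n_events = 0
        events = np.zeros_like(t)
        if is_fluct and spec.event_rate_hz > 0:
            n_prop = int(rng.poisson(spec.event_rate_hz * spec.duration_s))
            onsets = np.sort(rng.uniform(0.0, spec.duration_s, size=n_prop))
            if spec.event_min_gap_s > 0 and len(onsets) > 1:
                kept = [onsets[0]]
                for t0 in onsets[1:]:
                    if t0 - kept[-1] >= spec.event_min_gap_s:
                        kept.append(t0)
                onsets = np.array(kept)
            n_events = len(onsets)
            for t0 in onsets:
                mask = t >= t0
                events[mask] += spec.event_amp * _event_kernel(
                    t[mask] - t0, spec.event_tau_rise_s, spec.event_tau_decay_s
                )
        ratio = ratio + events
        if spec.noise_sd > 0:
            ratio = ratio + rng.normal(0.0, spec.noise_sd, size=len(t))

        # channel synthesis: donor dips during events, saturating at 50%
        # (overlapping transients would otherwise drive it non-positive)
        cer_bg = np.full_like(t, 30.0)
        ven_bg = np.full_like(t, 25.0)
        dip = np.clip(0.2 * events / max(spec.event_amp, 1e-12), 0.0, 0.5) if is_fluct else 0.0
        cer_corr = 100.0 * (1.0 - dip)
        ven_corr = ratio * cer_corr

        cid = f"cell{i:04d}"
        traces.append(
            DualChannelTrace(
                t=t,
                F_ven_soma=ven_bg + ven_corr,
                F_ven_bg=ven_bg,
                F_cer_soma=cer_bg + cer_corr,
                F_cer_bg=cer_bg,
                frame_rate_hz=fs,
                cell_id=cid,
                mouse_id=f"m{mouse_of[i]:02d}",
                group=spec.group,
            )
        )
        ratios[cid] = ratio
        rows.append(
            {
                "cell_id": cid,
                "mouse_id": f"m{mouse_of[i]:02d}",
                "group": spec.group,
                "fluctuating": is_fluct,
                "n_events": n_events,
                "frame_rate_hz": fs,
            }
        )
    return TraceSimResult(traces=traces, truth=pd.DataFrame(rows), ratios=ratios)


# --------------------------------------------------------------------------
# track generation


def gen_tracks(spec: TrackSimSpec) -> TrackSimResult:
    """Saltatory pause/move 3-D trajectories with localization jitter."""
    rng = np.random.default_rng(spec.seed)
    n_mig = int(round(spec.frac_migratory * spec.n_cells))
    mig_idx = set(rng.choice(spec.n_cells, size=n_mig, replace=False).tolist())
    mouse_of = rng.integers(0, spec.n_mice, size=spec.n_cells)

    t_min = 15.0 * np.arange(spec.n_intervals + 1)
    tracks, rows = [], []
    for i in range(spec.n_cells):
        start = rng.uniform(0.0, 200.0, size=3)
        pos = [start]
        n_moves = 0
        path = 0.0
        migratory = i in mig_idx
        for _ in range(spec.n_intervals):
            step = np.zeros(3)
            if migratory and rng.random() < spec.p_move:
                length = abs(rng.normal(spec.step_scale_um, 0.2 * spec.step_scale_um))
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                step = length * direction
                n_moves += 1
                path += length
            pos.append(pos[-1] + step)
        xyz = np.array(pos)
        if spec.jitter_um > 0:
            xyz = xyz + rng.normal(0.0, spec.jitter_um, size=xyz.shape)
        cid = f"cell{i:04d}"
        tracks.append(
            CellTrack(
                cell_id=cid,
                t_min=t_min,
                xyz_um=xyz,
                mouse_id=f"m{mouse_of[i]:02d}",
                group=spec.group,
                session="12dpi",
            )
        )
        rows.append(
            {
                "cell_id": cid,
                "mouse_id": f"m{mouse_of[i]:02d}",
                "group": spec.group,
                "migratory": migratory,
                "n_move_intervals": n_moves,
                "path_um": path,
            }
        )
    return TrackSimResult(tracks=tracks, truth=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# tree generation


def gen_trees(
    n: int,
    depth: int,
    seg_len_um: float,
    seed: int = 0,
    branch_prob: float = 1.0,
) -> TreeSimResult:
    """Random binary dendritic trees with exact TDBL/branch-count truth.

    Each tree is rooted at a soma node; at every level each prospective
    daughter segment exists with probability ``branch_prob`` (1.0 gives the
    full binary tree).  Segments are straight, seg_len_um long, in randomly
    perturbed semi-radial directions.  Truth bookkeeping is independent of
    the morphometry module: TDBL = number of segments x seg_len_um; a branch
    is counted whenever a segment starts at the soma or at a node retaining
    two daughters (single-daughter continuations extend the branch).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    trees, rows = [], []
    for k in range(n):
        ids = [1]
        types = [1]  # soma
        xyz = [np.zeros(3)]
        radii = [5.0]
        parents = [-1]
        n_edges = 0
        n_branches = 0
        next_id = 2
        # frontier: (node index, outgoing direction, level)
        frontier = [(0, None, 0)]
        while frontier:
            node, direction, level = frontier.pop()
            if level >= depth:
                continue
            # binary tree: up to two daughters; the root always keeps both so
            # every tree has an arbor, deeper nodes prune with branch_prob
            if level == 0 or branch_prob >= 1.0:
                kept = [0, 1]
            else:
                kept = [d for d in range(2) if rng.random() < branch_prob]
            starts_branch = (types[node] == 1) or (len(kept) >= 2)
            for _ in kept:
                if direction is None:
                    d = rng.normal(size=3)
                else:
                    d = direction + 0.8 * rng.normal(size=3)
                d = d / np.linalg.norm(d)
                xyz.append(xyz[node] + seg_len_um * d)
                ids.append(next_id)
                types.append(3)  # basal dendrite
                radii.append(0.5)
                parents.append(ids[node])
                n_edges += 1
                if starts_branch:
                    n_branches += 1
                frontier.append((len(ids) - 1, d, level + 1))
                next_id += 1
        tree = NeuronTree(
            ids=np.array(ids),
            types=np.array(types),
            xyz=np.array(xyz),
            radii=np.array(radii),
            parents=np.array(parents),
            name=f"tree{k:03d}",
        )
        trees.append(tree)
        rows.append(
            {"tree": f"tree{k:03d}", "tdbl_um": n_edges * seg_len_um,
             "n_branches": n_branches}
        )
    return TreeSimResult(trees=trees, truth=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# census generation


def gen_census_pair(
    n_cells: int,
    frac_survive: float,
    drift_um: float,
    fov: tuple[float, float, float] = DEFAULT_FOV_UM,
    margin: float = DEFAULT_MARGIN_UM,
    seed: int = 0,
    newcomer_frac: float = 0.2,
    sessions: tuple[str, str] = ("14dpi", "25dpi"),
) -> CensusSimResult:
    """Two-session survival censuses with known survivor ids.

    Survivors reappear displaced by a random direction with magnitude drawn
    uniformly in [drift_um/2, drift_um] (zero drift gives identical
    positions); non-survivors disappear; newcomers (fraction of n_cells,
    default 0.2, the continuing-arrival case) appear at fresh positions.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array(fov)
    xyz_a = rng.uniform(lo, hi, size=(n_cells, 3))
    ids_a = np.array([f"cell{i:04d}" for i in range(n_cells)])
    n_surv = int(round(frac_survive * n_cells))
    surv = np.zeros(n_cells, dtype=bool)
    surv[rng.choice(n_cells, size=n_surv, replace=False)] = True

    xyz_b_rows, ids_b = [], []
    for i in np.flatnonzero(surv):
        if drift_um > 0:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            mag = rng.uniform(drift_um / 2.0, drift_um)
            p = np.clip(xyz_a[i] + mag * direction, lo, hi)
        else:
            p = xyz_a[i]
        xyz_b_rows.append(p)
        ids_b.append(ids_a[i])
    n_new = int(round(newcomer_frac * n_cells))
    new_ids = [f"new{i:04d}" for i in range(n_new)]
    for i in range(n_new):
        xyz_b_rows.append(rng.uniform(lo, hi))
        ids_b.append(new_ids[i])

    census_a = FOVCensus(
        session=sessions[0], cell_ids=ids_a, xyz_um=xyz_a, fov_um=fov, margin_um=margin
    )
    census_b = FOVCensus(
        session=sessions[1],
        cell_ids=np.array(ids_b),
        xyz_um=np.array(xyz_b_rows).reshape(-1, 3),
        fov_um=fov,
        margin_um=margin,
    )
    truth = pd.DataFrame(
        {
            "cell_id": np.concatenate([ids_a, new_ids]),
            "survived": np.concatenate([surv, np.zeros(n_new, dtype=bool)]),
            "newcomer": np.concatenate(
                [np.zeros(n_cells, dtype=bool), np.ones(n_new, dtype=bool)]
            ),
        }
    )
    return CensusSimResult(census_a=census_a, census_b=census_b, truth=truth)


# --------------------------------------------------------------------------
# count generation


def gen_counts(spec: CountSimSpec) -> CountSimResult:
    """Negative-binomial count matrix with planted DEGs.

    Planted genes change by exactly 2**log2fc_de in expected expression in
    both overexpression groups relative to control (up or down at random per
    gene).  Dispersion 0 degenerates to deterministic rounded means, useful
    for exact normalization checks.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(mean=4.5, sigma=1.2, size=spec.n_genes)
    n_de = int(round(spec.frac_de * spec.n_genes))
    de = np.zeros(spec.n_genes, dtype=bool)
    de[rng.choice(spec.n_genes, size=n_de, replace=False)] = True
    sign = np.where(rng.random(spec.n_genes) < 0.5, 1.0, -1.0)
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]

    cols, labels = [], {}
    data = {}
    for g in spec.groups:
        fc = np.ones(spec.n_genes)
        if g != spec.groups[0]:
            fc = np.where(de, 2.0 ** (sign * spec.log2fc_de), 1.0)
        mu = base * fc
        q = mu / mu.sum()
        for s in range(spec.n_samples_per_group):
            name = f"{g}_{s + 1}"
            lib = rng.uniform(*spec.lib_size_range)
            mean = q * lib
            if spec.dispersion > 0:
                shape = 1.0 / spec.dispersion
                lam = rng.gamma(shape, mean / shape)
                counts = rng.poisson(lam)
            else:
                counts = np.round(mean).astype(int)
            data[name] = counts
            labels[name] = g
            cols.append(name)

    matrix = CountMatrix(
        counts=pd.DataFrame(data, index=genes),
        groups=pd.Series(labels),
    )
    truth = pd.DataFrame(
        {"gene": genes, "is_de": de, "log2fc": np.where(de, sign * spec.log2fc_de, 0.0)}
    )
    return CountSimResult(matrix=matrix, truth=truth)


# --------------------------------------------------------------------------
# odor trials


def gen_odor_trials(
    n_cells: int = 30,
    frac_responsive: float = 0.6,
    n_trials: int = 2,
    amp_drr: float = 0.15,
    noise_sd: float = 0.01,
    frame_rate_hz: float = 8.0,
    duration_s: float = 20.0,
    stim_onset_s: float = 8.0,
    stim_dur_s: float = 4.0,
    seed: int = 0,
) -> tuple[dict[str, list[OdorTrial]], pd.DataFrame]:
    """Odor trials with known responder labels.

    Responsive cells receive a sharp-rise transient (rise 0.2 s, decay 2 s,
    amplitude amp_drr in dR/R units) shortly after stimulus onset in every
    trial; all traces carry white ratio noise.  Returns trials grouped by
    cell plus the truth table.
    """
    rng = np.random.default_rng(seed)
    n_resp = int(round(frac_responsive * n_cells))
    resp_idx = set(rng.choice(n_cells, size=n_resp, replace=False).tolist())
    t = np.arange(0.0, duration_s, 1.0 / frame_rate_hz)
    trials: dict[str, list[OdorTrial]] = {}
    rows = []
    for i in range(n_cells):
        cid = f"cell{i:04d}"
        responsive = i in resp_idx
        cell_trials = []
        for _ in range(n_trials):
            baseline = 1.0
            ratio = baseline * (1.0 + rng.normal(0.0, noise_sd, size=len(t)))
            if responsive:
                t0 = stim_onset_s + rng.uniform(0.1, 0.6)
                mask = t >= t0
                ratio[mask] += baseline * amp_drr * _event_kernel(t[mask] - t0, 0.2, 2.0)
            cell_trials.append(
                OdorTrial(
                    t=t,
                    ratio=ratio,
                    frame_rate_hz=frame_rate_hz,
                    stim_onset_s=stim_onset_s,
                    stim_dur_s=stim_dur_s,
                    cell_id=cid,
                )
            )
        trials[cid] = cell_trials
        rows.append({"cell_id": cid, "responsive": responsive, "amp_drr": amp_drr if responsive else 0.0})
    return trials, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# immunofluorescence


def gen_if_measurements(
    n_fov: int = 10,
    n_abjgc_per_fov: int = 3,
    n_neun_per_fov: int = 40,
    planted_ratio: float = 19.7,
    neun_mean: float = 500.0,
    cv: float = 0.15,
    background: float = 50.0,
    seed: int = 0,
):
    """Per-FOV intensity sets with a planted abJGC/NeuN pCREB ratio."""
    from .quant_if import IFMeasurement

    rng = np.random.default_rng(seed)
    out = []
    for f in range(n_fov):
        neun_corr = neun_mean * rng.lognormal(0.0, cv, size=n_neun_per_fov)
        med = np.median(neun_corr)
        ab_corr = planted_ratio * med * rng.lognormal(0.0, cv, size=n_abjgc_per_fov)
        out.append(
            IFMeasurement(
                fov_id=f"fov{f:02d}",
                abjgc_intensity=ab_corr + background,
                neun_intensity=neun_corr + background,
                background=background,
            )
        )
    return out, planted_ratio


# --------------------------------------------------------------------------
# electrophysiology


def gen_ap_trace(
    onset_mv: float = -45.0,
    rest_mv: float = -70.0,
    noise_sd_mv: float = 0.1,
    tau_up_ms: float = 0.15,
    sampling_rate_hz: float = 20_000.0,
    stim_start_ms: float = 200.0,
    stim_end_ms: float = 400.0,
    duration_ms: float = 500.0,
    with_ap: bool = True,
    seed: int = 0,
) -> tuple[VoltageTrace, float]:
    """Current-clamp record with an (optional) action potential whose
    depolarization onset voltage is known analytically.

    The stimulus charges the membrane linearly from rest to ``onset_mv``;
    from onset the voltage rises exponentially with time constant
    ``tau_up_ms`` (capped at +30 mV) then repolarizes.  Returns the trace and
    the true onset voltage.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_rate_hz
    t = np.arange(0.0, duration_ms, dt)
    v = np.full_like(t, rest_mv)
    if with_ap:
        ramp_dur = 20.0  # ms to charge from rest to onset
        t_on = stim_start_ms + ramp_dur
        ramp = (t >= stim_start_ms) & (t < t_on)
        v[ramp] = rest_mv + (onset_mv - rest_mv) * (t[ramp] - stim_start_ms) / ramp_dur
        up = (t >= t_on)
        arg = np.minimum((t[up] - t_on) / tau_up_ms, 50.0)
        v[up] = onset_mv + 1.0 * (np.exp(arg) - 1.0)
        peak_mask = v > 30.0
        v[peak_mask] = 30.0
        # repolarize after the first peak sample
        if peak_mask.any():
            i_peak = int(np.flatnonzero(peak_mask)[0])
            decay = np.arange(len(t) - i_peak) * dt
            v[i_peak:] = rest_mv + (30.0 - rest_mv) * np.exp(-decay / 2.0)
    else:
        stim = (t >= stim_start_ms) & (t <= stim_end_ms)
        v[stim] = rest_mv + 5.0  # subthreshold depolarization step
    v = v + rng.normal(0.0, noise_sd_mv, size=len(t))
    trace = VoltageTrace(
        t_ms=t,
        v_mv=v,
        sampling_rate_hz=sampling_rate_hz,
        stim_start_ms=stim_start_ms,
        stim_end_ms=stim_end_ms,
    )
    return trace, onset_mv


def gen_iv_table(
    rmp_mv: float = -82.0,
    r_in_mohm: float = 500.0,
    holding_mv: tuple[float, ...] = (-110.0, -90.0, -70.0),
    noise_pa: float = 0.0,
    seed: int = 0,
) -> tuple[IVTable, float]:
    """I-V table consistent with a linear membrane: I = (V - RMP)/R_in."""
    rng = np.random.default_rng(seed)
    v = np.array(holding_mv)
    i = (v - rmp_mv) / r_in_mohm * 1e3  # mV/MOhm = nA -> pA
    if noise_pa > 0:
        i = i + rng.normal(0.0, noise_pa, size=len(i))
    return IVTable(v_mv=v, i_pa=i), rmp_mv
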