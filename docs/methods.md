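# Methods

This note documents the models, estimators, numerical choices, and the
synthetic-data conditions behind `abneuro`, in the spirit of the methods
documentation of packages like statsmodels or msprime: what each procedure
assumes, which parameters matter, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Ratiometric trace analysis

The Twitch-2B indicator reports [Ca²⁺]ᵢ as the ratio of background-corrected
acceptor (cpVenus^CD) over donor (mCerulean3) fluorescence,

    R(t) = (F_ven,soma − F_ven,bg) / (F_cer,soma − F_cer,bg).

A non-positive donor denominator is treated as a hard error naming the sample
index: it indicates a background ROI brighter than the soma, not a value to
clamp. Filtering uses a 4th-order Butterworth lowpass at 0.6 Hz applied
forward–backward (`sosfiltfilt`), i.e. zero phase and unit DC gain; the order
is a package choice (it is exposed as a parameter) — the effective response
is the squared one-pass magnitude.

Per-cell features:

- **Basal ratio** — mean of the lowest ⌈0.1·N⌉ sample values. Selecting by
  value sort is equivalent to the lowest decile of the amplitude histogram.
- **Maximum ratio** — maximum over all *full* sliding windows of
  round(1.5 s × frame rate) samples; edge windows are not padded, avoiding
  edge bias on 2-min traces.
- **AUC/s** — trapezoidal integral of (R − baseline) divided by the recording
  duration. The baseline defaults to the trace's own basal ratio (the
  event-area reading); zero-baseline is selectable.
- **Mid-reference crossings** — state levels estimated by the bimodal
  histogram method: 100 bins over the sample range, the low (high) state
  level is the most populated bin in the lower (upper) half of the bins, ties
  broken toward the extremes; the mid-reference level is their midpoint and a
  crossing is a pair of consecutive samples strictly straddling it. A
  constant trace yields 0 crossings with a warning.

Whether crossings are counted on the filtered or raw trace is configurable;
the default is filtered, matching the order in which the operations are
described for the original analysis.

## Fluctuation classification

Pooled integer crossing counts are fitted with 1-D Gaussian mixtures for
k = 1..5 (10 restarts, k-means++ initialization, fixed seed). Two departures
from a textbook BIC-argmin fit, both forced by the integer, right-skewed
nature of count data:

- **Variance floor 0.5** (`reg_covar`): without it a component collapses onto
  a single repeated integer value, and BIC then prefers spuriously large k.
  Any physical count mode has at least Poisson-scale variance, so a floor at
  the sub-Poisson scale removes the degeneracy without touching genuine
  structure.
- **Parsimonious k**: the selected k is the smallest whose BIC lies within 10
  of the minimum (the Kass–Raftery "very strong evidence" threshold). With
  enough cells, argmin-BIC models the skew of a single activity mode with two
  Gaussians; the extra component improves the density fit but has no cluster
  meaning, and a min-mean-only labeling rule would then misread it.

The minimum-mean component is labelled "without fluctuations", all others
"with" (for three genuinely separated modes, "with" is the union of the two
upper ones). If k = 1 is selected, all cells are labelled "without" when the
component mean is ≤ 2 crossings, else "with". Counts are fitted untransformed;
a log1p option exists but is not the default — with any fixed variance floor
it degenerates (the floor is far too wide on the log scale).

Group summaries are per-mouse fractions reported as mean ± SEM over mice.
Group comparisons follow the normality-gated rule: Shapiro–Wilk per group at
α = 0.05; all normal → Student's t-test (2 groups) or one-way ANOVA with
Tukey's HSD (≥ 3); otherwise Mann–Whitney U or Kruskal–Wallis with Dunn's
multiple comparisons (rank-based z with tie correction, Bonferroni-adjusted).
No correction beyond Tukey/Dunn is applied. Groups need n ≥ 3 (Shapiro–Wilk
is undefined below that).

## Odor-evoked responses

ΔR/R = (R − R₀)/R₀ with R₀ the mean over a 5-s pre-stimulus baseline
(configurable). Smoothing uses a binomial (Pascal-row) kernel of
round(0.3 s × frame rate) taps forced odd (≥ 3), reflective boundaries, exact
unit DC gain. The noise trace is raw minus smoothed ΔR/R; its SD over the
baseline window is the noise scale.

Detection scans [onset, onset + 4 s + 2 s margin] by normalized
cross-correlation of the smoothed trace against a sharp-rise template
(difference of exponentials, rise 0.2 s, decay 2.0 s, resampled to the
trial's frame rate; both constants configurable). A window qualifies as a
candidate only when its correlation reaches 0.85 — the match criterion that
makes this template matching rather than a bare peak search; without it,
extrema of smoothed noise pass the amplitude rule in roughly 10% of null
trials. The best candidate *responds* when its peak smoothed ΔR/R is
strictly greater than 3× the noise SD (an inclusive-boundary flag exists).
On noiseless synthetic input the SD is zero and the rule degenerates to
amplitude > 0, with a warning. A cell is *responsive* when at least half of
its trials responded (the ≥ 1-of-2 reading for two trials); amplitude and
AUC are medians over responding trials.

## Migration

All distances are Euclidean in 3-D; X/Y from the imaging plane, Z the depth
from the dura, no refractive-index correction. Speeds divide each step by its
actual inter-stack time and are expressed per 15 min, so a missed stack
contributes a halved rate rather than being dropped. A cell is moving when
any step exceeds 4 µm strictly; the same 4-µm gate (a resolution-based
tolerance, configurable) flags position changes between sessions. Metrics
are invariant under rigid motions of the coordinate frame.

## Morphometry

SWC reconstructions are validated for a unique root, existing parents and
acyclicity. TDBL sums Euclidean edge lengths, excluding edges with both
endpoints of soma type. A *branch* is a maximal unbranched path between
topological events (soma, branch point, terminal); the primary stem counts.
Sholl intersections are computed exactly per segment by solving the quadratic
|a + t(b−a) − c|² = r² on t ∈ (0, 1]: transversal roots count once each, a
tangency (double root) counts once, and roots at t = 0 belong to the
preceding segment so a vertex exactly on a shell is counted exactly once.
The sphere centre is the centroid of soma-type nodes. A 2-D (circle) variant
exists for thin-slice data. Sholl group comparison applies the per-radius
normality-gated tests — a deliberate simplification; a Poisson mixed-effects
model over the whole profile is out of scope.

## Survival

Censuses are first margin-filtered: cells within 100 µm of the XY border are
excluded (boundary inclusive — a cell at exactly 100 µm is retained); Z is
unrestricted. Matching is a one-to-one optimal assignment (Hungarian
algorithm) on the 3-D distance matrix with pairs beyond the 4-µm gate
forbidden; the gate boundary is inclusive (an offset of exactly 4 µm
survives). Optimal assignment, unlike greedy nearest-neighbour, is
order-independent and therefore reproducible, and newcomers cannot steal a
within-gate match from a true survivor. Whether the gate should be 2-D or
3-D is not decidable from the available description; 3-D is the default and
XY-only is a flag. The survival rate is matched cells over retained
session-a cells.

## Immunofluorescence

Relative pCREB level per abJGC: (F_abJGC − bg) / median(F_NeuN − bg), with a
per-slice scalar background (estimated upstream from secondary-antibody-only
controls). Kv1.2: (F_soma − bg) / (F_neuropil − bg). Intensities below
background clamp to 0 with a warning (noise floor); a non-positive NeuN
median marks the FOV unusable and raises. Both ratios are scale-invariant
only when the background is zero or scaled jointly — the tests assert the
exact behaviour in both regimes.

## Electrophysiology

AP threshold: dV/dt by central differences on the 20-kHz record; σ is the SD
of dV/dt over a 100-ms pre-stimulus baseline (length configurable and
reported); the threshold is V at the first sample of the earliest run where
dV/dt > 3σ sustained for ≥ 0.2 ms. The sustain requirement is a package
addition — at 20 kHz the bare 3σ rule fires on single noise samples. Two
cross-check modes: a fixed rate-of-rise criterion (default 50 V/s — i.e.
50 mV/ms) and the first peak of the third derivative. Input resistance is the
least-squares slope of ΔV on steady-state ΔI through the origin (Ohm's law;
mV/pA × 10³ = MΩ). Resting potential is the zero-current intercept of the
least-squares I–V line through the three holding points.

## Transcriptomics

CPM uses raw column sums as library sizes (TMM is available as an option but
is not part of the filtering rule). The expression filter is the literal
exclusion rule — drop genes with CPM < 1 in ≥ 2 samples; the wording is
ambiguous between this and the complementary keep-rule (keep if CPM ≥ 1 in
≥ 2 samples), so both are implemented and neither is asserted as the original
behaviour. DEG classification is the printed fold-change rule on group-mean
CPM with a 0.5 pseudo-count: |FC| > 2 (strict) between control and the Kv
group *or* control and the Kir group (union; intersection selectable). The
negative-binomial GLM testing stage that accompanied this rule in the
original workflow is intentionally out of scope and outputs are labelled as
fold-change-only classifications. Module summaries report log2(CPM + 0.5) of
member genes per sample with group labels, suitable for the normality-gated
group tests; a housekeeping set serves as the negative control.

## Synthetic-data conditions

The generator defaults are the study-like conditions under which all
recovery benchmarks run; they were fixed at design time and the acceptance
tolerances were not adjusted to them.

- **Traces**: 60 cells across 8 mice, 57.5% fluctuating, 120 s at a per-cell
  frame rate drawn uniformly in 7–10 Hz (forcing every trace operation to be
  sampling-rate aware). Ratio = baseline 1.0 + slow drift + events + white
  noise (SD 0.005). Events are peak-normalized double exponentials (rise
  0.5 s, decay 2 s, amplitude 0.5) at Poisson onsets of rate 0.15 Hz thinned
  to a 2.5-s refractory gap — unbounded stacking would stretch the amplitude
  histogram and pull the upper state level onto rare stacked peaks, outside
  the regime the state-level method is valid in. The drift (two
  low-frequency sinusoids, periods 40–120 s, total amplitude 10× noise SD)
  is what gives quiet cells their *low* crossing counts: the mid-level of a
  drift-free noise trace sits inside the noise band, where the crossing rate
  of band-limited noise is amplitude-independent and large (~0.7/s for a
  0.6-Hz band, Rice's formula) and the with/without bimodality would invert.
  The drift amplitude is tied to the noise SD so that a noiseless spec
  degenerates to an exactly constant trace. The two fluorescence channels
  are synthesized so the computed ratio reproduces the stored ground truth
  to machine precision, with the donor dipping (up to 50%) during events as
  a FRET sensor does.
- **Tracks**: 17 positions at 15-min spacing; migratory cells move in a
  given interval with probability 0.3 by a step of mean 8 µm in a uniform
  3-D direction; all positions carry 0.5 µm localization jitter.
- **Trees**: binary topology with per-daughter retention probability,
  straight segments of fixed length in perturbed semi-radial directions;
  TDBL and branch-count truth comes from construction-time bookkeeping, not
  from the morphometry code.
- **Censuses**: uniform positions in the 635 × 635 × 200 µm FOV; survivors
  reappear displaced by a magnitude uniform in [drift/2, drift]; newcomers
  (20% of the cohort, the continuing-arrival case) appear at fresh
  positions.
- **Counts**: lognormal baseline means, gamma–Poisson (negative binomial)
  sampling with dispersion 0.1, library sizes uniform in 0.8–1.2 M;
  planted DEGs change by exactly 2^±2 in both overexpression groups.
  Dispersion 0 degenerates to deterministic rounded means for exact
  normalization checks. Because planted changes alter the library total,
  observed CPM fold changes equal the planted ones up to a small common
  compositional factor — as in real sequencing data.

What these benchmarks show: that each estimator recovers the quantity it
defines under its own stated noise model, with correct boundary semantics
and invariances. What they do not show: robustness to motion artefacts,
neuropil contamination, segmentation errors, registration failure between
sessions, amplitude-correlated noise, or library-composition effects beyond
the simple shift above — none of which the generator emulates (traces are
ROI-level, not pixel-level, by design).

## Problem sizes

Benchmarks run at desk scale, chosen to keep the full suite around half a
minute: 60-cell cohorts (20 seeds × 3 fractions) for clustering recovery,
100 random instances per oracle-equivalence check, 2 000-gene matrices with
n = 5 per group for the DEG power check (the study-like n = 2 per group is
the generator default).
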