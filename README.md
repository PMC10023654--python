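# abneuro

Quantitative analysis pipeline for longitudinal in vivo studies of adult-born
juxtaglomerular cells (abJGCs) — interneurons that arrive in the olfactory-bulb
glomerular layer through adult neurogenesis. The package implements, as tested
and reusable library code, the full analysis layer such a study needs:

- **Calcium traces** — the ratiometric FRET indicator Twitch-2B is read as
  R = (F_acceptor,soma − F_acceptor,bg) / (F_donor,soma − F_donor,bg); traces
  are lowpass-filtered (4th-order zero-phase Butterworth, 0.6 Hz) and
  summarised per cell by the basal ratio (mean of the lowest 10% of samples),
  the maximum ratio (peak 1.5-s sliding average), AUC per second, and the
  number of mid-reference level crossings.
- **Fluctuation classification** — a 1-D Gaussian mixture over pooled
  crossing counts, with BIC model selection, splits cells into
  with/without-[Ca²⁺]ᵢ-fluctuation clusters; fractions are summarised per
  mouse and compared with Shapiro–Wilk-gated parametric/nonparametric tests
  (t-test / ANOVA + Tukey vs Mann–Whitney / Kruskal–Wallis + Dunn).
- **Odor responses** — ΔR/R against a pre-stimulus baseline, binomial
  smoothing (0.3 s), sharp-rise template matching, and the 3×SD-of-baseline-
  noise amplitude criterion.
- **Migration** — 3-D migration distance D = √(ΔX² + ΔY² + ΔZ²) per 15-min
  interval; a cell is *moving* when any step exceeds 4 µm (the axial
  resolution limit of 2-µm-step stacks).
- **Morphometry** — total dendritic branch length (TDBL), branch counts, and
  3-D Sholl profiles (sphere crossings at 10-µm radius steps) from SWC
  reconstructions.
- **Survival** — two-session censuses in a 635 × 635 × 200 µm field of view,
  100-µm XY safety margin, one-to-one optimal matching with a ≤ 4 µm offset
  tolerance.
- **Immunofluorescence** — relative pCREB level
  (F_abJGC − bg) / median(F_NeuN − bg) and the Kv1.2 soma/neuropil ratio.
- **Electrophysiology** — AP threshold from the 3×SD dV/dt rule, input
  resistance from hyperpolarizing steps, resting potential from the
  zero-current intercept of the I–V line.
- **Transcriptomics** — CPM normalization, the "< 1 CPM in ≥ 2 samples"
  expression filter, the > 2-fold change DEG classification between a control
  and two potassium-channel overexpression groups (Kv1.2, Kir2.1), and
  gene-module expression summaries.

A first-class **synthetic-data generator** (`abneuro.synthetic_data`)
produces every input with known ground truth — two-channel FRET traces with
double-exponential events, saltatory pause/move trajectories, branching
dendritic trees, survival census pairs, negative-binomial count matrices with
planted twofold changes — so every stage is verifiable without raw imaging
data.

## Worked example

Classify a synthetic cohort of 60 cells (8 mice, 57.5% of cells truly
fluctuating) from raw two-channel traces:

```python
import numpy as np
from abneuro import synthetic_data as sd, calcium_traces as ct, fluctuation_clustering as fc

spec = sd.TraceSimSpec(n_cells=60, frac_fluctuating=0.575, seed=1)
res = sd.gen_traces(spec)
samples = [
    fc.CrossingSample(t.cell_id, t.mouse_id, t.group,
                      ct.count_midcrossings(ct.lowpass_filter(ct.compute_ratio(t))))
    for t in res.traces
]
cl = fc.fit_crossing_gmm(samples, seed=0)
print("components (k):", cl.k_selected)
print("component means:", np.round(np.sort(cl.means.ravel()), 1))
print(fc.fraction_with_fluctuations(cl, by="group").to_string(index=False))
```

Output:

```
components (k): 2
component means: [ 4.  22.8]
  group  n_mice  mean_fraction  sem_fraction
control       8       0.592851       0.08186
```

BIC selects two clusters: quiet cells cross their mid-reference level ~4
times in 2 min (slow baseline drift only), fluctuating cells ~23 times
(about twice per calcium transient). The recovered per-mouse mean fraction,
0.59 ± 0.08 SEM, brackets the planted 0.575.

The same pipeline is scriptable from the shell:

```bash
abneuro simulate traces --seed 1 --out sim/
abneuro traces --in sim/ --out features.csv
abneuro fluctuations --in features.csv --seed 0 --out clusters/
```

`abneuro --help` lists the commands for the other stages
(`odor`, `migrate`, `morpho`, `survive`, `ifquant`, `ephys`, `rnaseq`).

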