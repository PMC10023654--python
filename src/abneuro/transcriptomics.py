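"""Expression filtering, fold-change DEG classification, and gene-module
summaries for raw RNA-seq count matrices.

Counts are normalized to counts per million (CPM) against raw library sizes.
The expression filter drops transcripts with CPM < 1 in at least two samples
(the literal exclusion rule; the complementary keep-rule is selectable).  A
gene is called differentially expressed when its group-mean CPM (with a 0.5
pseudo-count) changes more than twofold between control and either
potassium-channel overexpression group (Kv1.2 or Kir2.1) — the printed
classification rule, applied here without the negative-binomial GLM testing
stage that accompanied it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "DegCall",
    "cpm",
    "expression_filter",
    "call_degs",
    "module_summary",
    "deg_percentages",
    "read_counts_tsv",
]

PSEUDOCOUNT = 0.5
DEFAULT_GROUPS = ("control", "kv", "kir")


@dataclass
class CountMatrix:
    """Gene x sample raw counts with a sample -> group map."""

    counts: pd.DataFrame  # index: gene, columns: sample
    groups: pd.Series  # index: sample, values: group label

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[self.counts.columns]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


@dataclass
class DegCall:
    gene: str
    log2fc_kv: float
    log2fc_kir: float
    is_deg: bool


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: counts * 1e6 / library size, per sample column."""
    lib = counts.library_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    return counts.counts * 1e6 / lib


def expression_filter(
    counts: CountMatrix,
    cpm_min: float = 1.0,
    n_samples: int = 2,
    rule: str = "exclude",
) -> CountMatrix:
    """Drop lowly expressed transcripts.

    ``rule="exclude"`` (literal): drop genes with CPM < cpm_min in >=
    n_samples samples.  ``rule="keep"``: keep genes with CPM >= cpm_min in >=
    n_samples samples.  The two differ only for genes low in between
    n_samples and (total - n_samples) samples.
    """
    c = cpm(counts)
    low = (c < cpm_min).sum(axis=1)
    if rule == "exclude":
        keep = low < n_samples
    elif rule == "keep":
        keep = (c >= cpm_min).sum(axis=1) >= n_samples
    else:
        raise ValueError(f"rule must be 'exclude' or 'keep', got {rule!r}")
    return CountMatrix(counts=counts.counts.loc[keep], groups=counts.groups)


def _group_mean_cpm(counts: CountMatrix) -> pd.DataFrame:
    c = cpm(counts)
    return c.T.groupby(counts.groups).mean().T


def call_degs(
    counts: CountMatrix,
    fc_threshold: float = 2.0,
    groups: tuple[str, str, str] = DEFAULT_GROUPS,
    combine: str = "union",
) -> pd.DataFrame:
    """Fold-change DEG classification on group-mean CPM.

    A gene is a DEG when |fold change| > fc_threshold (strict) between
    control and the Kv group, or between control and the Kir group
    (``combine="union"``; ``"intersection"`` requires both).  Fold changes
    use a 0.5 pseudo-count on the group-mean CPM.  Returns a frame indexed
    by gene with log2fc_kv, log2fc_kir, is_deg.
    """
    ctrl, kv, kir = groups
    present = set(counts.groups)
    for g in groups:
        if g not in present:
            raise ValueError(f"group {g!r} missing from sample map")
    gm = _group_mean_cpm(counts)
    l2 = {}
    for name, g in (("kv", kv), ("kir", kir)):
        l2[name] = np.log2(gm[g] + PSEUDOCOUNT) - np.log2(gm[ctrl] + PSEUDOCOUNT)
    thr = np.log2(fc_threshold)
    hit_kv = np.abs(l2["kv"]) > thr
    hit_kir = np.abs(l2["kir"]) > thr
    if combine == "union":
        is_deg = hit_kv | hit_kir
    elif combine == "intersection":
        is_deg = hit_kv & hit_kir
    else:
        raise ValueError(f"combine must be 'union' or 'intersection', got {combine!r}")
    return pd.DataFrame(
        {"log2fc_kv": l2["kv"], "log2fc_kir": l2["kir"], "is_deg": is_deg}
    )


def deg_percentages(n_deg: int, n_total: int) -> tuple[float, float]:
    """DEG percentage and its complement from classification counts."""
    if not (0 <= n_deg <= n_total) or n_total <= 0:
        raise ValueError("need 0 <= n_deg <= n_total, n_total > 0")
    pct = 100.0 * n_deg / n_total
    return pct, 100.0 - pct


def module_summary(
    counts: CountMatrix,
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-module expression distributions across samples.

    For each named gene set, returns the log2(CPM + 0.5) of every member gene
    in every sample, tidy: module, gene, sample, group, log2_cpm.  A module
    whose genes are all absent from the matrix raises, listing them.
    """
    c = cpm(counts)
    logc = np.log2(c + PSEUDOCOUNT)
    rows = []
    for module, genes in gene_sets.items():
        present = [g for g in genes if g in logc.index]
        if not present:
            raise ValueError(f"module {module!r}: no member genes in matrix "
                             f"(missing: {sorted(genes)})")
        sub = logc.loc[present]
        melted = sub.reset_index(names="gene").melt(
            id_vars="gene", var_name="sample", value_name="log2_cpm"
        )
        melted.insert(0, "module", module)
        melted["group"] = melted["sample"].map(counts.groups).to_numpy()
        rows.append(melted)
    return pd.concat(rows, ignore_index=True)


def read_counts_tsv(counts_path, groups_path) -> CountMatrix:
    """Genes x samples TSV (first column gene id) plus a two-column
    sample/group TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    g = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts=counts, groups=g)
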