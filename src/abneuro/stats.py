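"""Normality-gated group comparison.

The study's convention: Shapiro-Wilk on every group at alpha = 0.05; if all
groups pass, use the parametric route (Student's t-test for two groups, one-way
ANOVA with Tukey's HSD post hoc for three or more), otherwise the nonparametric
route (Mann-Whitney U, or Kruskal-Wallis with Dunn's multiple-comparisons post
hoc).  The paired flag switches to paired t-test / Wilcoxon signed-rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestReport", "compare_groups", "dunn_posthoc"]

ALPHA_NORMALITY = 0.05


@dataclass
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    normality: dict[str, bool]
    parametric: bool
    posthoc: pd.DataFrame | None = None
    group_n: dict[str, int] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's multiple-comparisons test after Kruskal-Wallis.

    Pairwise z statistics on mean ranks of the pooled sample with tie
    correction; p-values are Bonferroni-adjusted over all pairs, following the
    convention of common statistics packages.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = float(ranks[start : start + k].mean())
        sizes[g] = k
        start += k
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p_value": p})
    return pd.DataFrame(rows)


def _tukey_table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    res = sps.tukey_hsd(*(groups[g] for g in names))
    rows = []
    for i, j in combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": res.statistic[i, j],
                "p_value": res.pvalue[i, j],
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    groups: dict[str, "np.ndarray | list[float]"],
    paired: bool = False,
    alpha_normality: float = ALPHA_NORMALITY,
) -> TestReport:
    """Compare ≥2 groups with the normality-gated test-selection rule.

    Parameters
    ----------
    groups
        Mapping group label -> 1-D samples; every group needs n >= 3 (the
        Shapiro-Wilk test is undefined below that).
    paired
        Use paired t-test / Wilcoxon signed-rank for two groups of equal size.
    """
    g = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in g.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has n={len(v)} < 3 (Shapiro-Wilk undefined)")
    normality = {}
    for k, v in g.items():
        if np.ptp(v) == 0:  # Shapiro-Wilk undefined for constant data
            normality[k] = False
        else:
            normality[k] = bool(sps.shapiro(v).pvalue > alpha_normality)
    parametric = all(normality.values())
    vals = list(g.values())
    posthoc = None

    if len(g) == 2:
        a, b = vals
        if paired:
            if len(a) != len(b):
                raise ValueError("paired comparison needs equal group sizes")
            if parametric:
                r = sps.ttest_rel(a, b)
                name = "paired t-test"
            else:
                r = sps.wilcoxon(a, b)
                name = "Wilcoxon signed-rank"
        else:
            if parametric:
                r = sps.ttest_ind(a, b)
                name = "Student's t-test"
            else:
                r = sps.mannwhitneyu(a, b, alternative="two-sided")
                name = "Mann-Whitney U"
        stat, p = float(r.statistic), float(r.pvalue)
    else:
        if parametric:
            r = sps.f_oneway(*vals)
            name = "one-way ANOVA + Tukey"
            posthoc = _tukey_table(g)
        else:
            r = sps.kruskal(*vals)
            name = "Kruskal-Wallis + Dunn"
            posthoc = dunn_posthoc(g)
        stat, p = float(r.statistic), float(r.pvalue)

    return TestReport(
        test_name=name,
        statistic=stat,
        p_value=p,
        normality=normality,
        parametric=parametric,
        posthoc=posthoc,
        group_n={k: len(v) for k, v in g.items()},
    )
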