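"""Classify cells into with/without calcium-fluctuation clusters.

A 1-D Gaussian mixture model is fitted to the pooled per-cell mid-reference
crossing counts for k = 1..k_max components and the Bayesian information
criterion picks k.  The component with the smallest mean is labelled "without
fluctuations"; cells in all other components are "with fluctuations".  Group
summaries are per-mouse fractions (mean +/- SEM over mice), compared with the
normality-gated tests in :mod:`abneuro.stats`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .stats import TestReport, compare_groups  # re-exported: shared test logic

__all__ = [
    "CrossingSample",
    "ClusterResult",
    "TestReport",
    "fit_crossing_gmm",
    "fraction_with_fluctuations",
    "compare_groups",
]


@dataclass
class CrossingSample:
    cell_id: str
    mouse_id: str
    group: str
    n_crossings: int

    def __post_init__(self) -> None:
        if self.n_crossings < 0:
            raise ValueError("n_crossings must be >= 0")


@dataclass
class ClusterResult:
    """Fitted mixture and the derived binary fluctuation labels."""

    k_selected: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    bic: dict[int, float]
    labels: pd.DataFrame  # cell_id, mouse_id, group, n_crossings, component, fluctuating
    fluctuating_components: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def fit_crossing_gmm(
    samples: list[CrossingSample],
    k_max: int = 5,
    seed: int = 0,
    n_init: int = 10,
    log_transform: bool = False,
    single_component_threshold: float = 2.0,
    reg_covar: float = 0.5,
    bic_parsimony_delta: float = 10.0,
) -> ClusterResult:
    """Fit 1-D GMMs for k = 1..k_max on pooled crossing counts, select by BIC.

    The minimum-mean component is "without fluctuations".  If BIC selects a
    single component, all cells share one label: "without" when the component
    mean is at or below ``single_component_threshold`` crossings, else "with".
    ``log_transform`` fits on log1p(counts) instead of raw counts.

    ``reg_covar`` floors component variances at 0.5.  Crossing counts are
    integers, so without a floor a component can collapse onto one repeated
    count value and inflate k via BIC; and any physical count mode carries at
    least Poisson-scale variance, so a floor at the sub-Poisson scale also
    guards against marginal oversplits of the skewed low-count mode.

    k is the smallest value whose BIC lies within ``bic_parsimony_delta``
    (default 10, the Kass-Raftery "very strong evidence" threshold) of the
    minimum: count modes are right-skewed, so with enough cells a pure argmin
    splits one activity mode into two Gaussians even though the extra
    component carries no cluster meaning.
    """
    if len(samples) < 2 * k_max:
        raise ValueError(f"need >= {2 * k_max} samples for k_max={k_max}")
    counts = np.array([s.n_crossings for s in samples], dtype=float)
    x = np.log1p(counts) if log_transform else counts
    X = x.reshape(-1, 1)

    if np.ptp(x) == 0:
        warnings.warn("all crossing counts identical: k=1 degenerate fit", stacklevel=2)
        k_sel = 1
        means = np.array([x[0]])
        variances = np.array([0.0])
        weights = np.array([1.0])
        bics = {1: float("nan")}
        comp = np.zeros(len(x), dtype=int)
    else:
        fits: dict[int, GaussianMixture] = {}
        bics = {}
        for k in range(1, k_max + 1):
            gm = GaussianMixture(
                n_components=k,
                n_init=n_init,
                init_params="k-means++",
                random_state=seed,
                covariance_type="full",
                reg_covar=reg_covar,
            )
            gm.fit(X)
            fits[k] = gm
            bics[k] = float(gm.bic(X))
        best = min(bics.values())
        k_sel = min(k for k, v in bics.items() if v <= best + bic_parsimony_delta)
        gm = fits[k_sel]
        means = gm.means_.ravel()
        variances = gm.covariances_.reshape(k_sel)
        weights = gm.weights_.ravel()
        comp = gm.predict(X)

    if k_sel == 1:
        mean_raw = float(np.expm1(means[0])) if log_transform else float(means[0])
        fluct = np.full(len(x), mean_raw > single_component_threshold)
        fluct_comps = np.array([0], dtype=int) if fluct[0] else np.array([], dtype=int)
    else:
        without = int(np.argmin(means))
        fluct = comp != without
        fluct_comps = np.array([i for i in range(k_sel) if i != without], dtype=int)

    labels = pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in samples],
            "mouse_id": [s.mouse_id for s in samples],
            "group": [s.group for s in samples],
            "n_crossings": counts.astype(int),
            "component": comp,
            "fluctuating": fluct,
        }
    )
    return ClusterResult(
        k_selected=k_sel,
        means=means,
        variances=variances,
        weights=weights,
        bic=bics,
        labels=labels,
        fluctuating_components=fluct_comps,
    )


def fraction_with_fluctuations(
    result: ClusterResult, by: str = "mouse"
) -> pd.DataFrame:
    """Fraction of cells labelled 'with fluctuations'.

    ``by="mouse"`` returns one row per mouse (mouse_id, group, n_cells,
    fraction); ``by="group"`` summarises the per-mouse fractions as
    mean +/- SEM per group, which is the study's reporting unit.
    """
    lab = result.labels
    per_mouse = (
        lab.groupby(["group", "mouse_id"], sort=True)
        .agg(n_cells=("fluctuating", "size"), fraction=("fluctuating", "mean"))
        .reset_index()
    )
    empty = per_mouse["n_cells"] == 0
    if empty.any():
        warnings.warn("mice with 0 cells excluded from fractions", stacklevel=2)
        per_mouse = per_mouse[~empty]
    if by == "mouse":
        return per_mouse
    if by == "group":
        return (
            per_mouse.groupby("group", sort=True)["fraction"]
            .agg(
                n_mice="size",
                mean_fraction="mean",
                sem_fraction=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            )
            .reset_index()
        )
    raise ValueError(f"by must be 'mouse' or 'group', got {by!r}")
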