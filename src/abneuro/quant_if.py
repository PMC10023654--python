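"""Normalized immunofluorescence quantification.

Two readouts: the relative pCREB level of an adult-born juxtaglomerular cell
(abJGC) — its background-corrected pCREB fluorescence divided by the median
background-corrected pCREB fluorescence of the NeuN-positive mature neurons
in the same field of view — and the relative Kv1.2 expression level, somatic
fluorescence over surrounding-neuropil fluorescence, both background
corrected.  Intensities arrive already extracted from ROIs; all values are
arbitrary fluorescence units, background is a per-slice scalar estimated from
secondary-antibody-only negative controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IFMeasurement",
    "KvMeasurement",
    "relative_pcreb",
    "kv_expression_ratio",
    "pcreb_table",
]


@dataclass
class IFMeasurement:
    """pCREB intensities for one FOV: the abJGCs of interest and the NeuN+
    reference population, plus the slice background scalar."""

    fov_id: str
    abjgc_intensity: np.ndarray  # one value per abJGC in the FOV
    neun_intensity: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        self.abjgc_intensity = np.atleast_1d(np.asarray(self.abjgc_intensity, dtype=float))
        self.neun_intensity = np.atleast_1d(np.asarray(self.neun_intensity, dtype=float))
        if self.abjgc_intensity.size < 1:
            raise ValueError("need at least one abJGC intensity")
        if np.any(self.abjgc_intensity < 0) or np.any(self.neun_intensity < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class KvMeasurement:
    soma_intensity: float
    neuropil_intensity: float
    cell_id: str = ""


def _clamp_corrected(values: np.ndarray, bg: float, what: str) -> np.ndarray:
    corr = values - bg
    if np.any(corr < 0):
        warnings.warn(
            f"{what}: background exceeds intensity, clamping to 0", stacklevel=3
        )
        corr = np.clip(corr, 0.0, None)
    return corr


def relative_pcreb(m: IFMeasurement) -> np.ndarray:
    """Relative pCREB level per abJGC:
    (F_abJGC - bg) / median(F_NeuN - bg)."""
    if m.neun_intensity.size == 0:
        raise ValueError(f"FOV {m.fov_id}: no NeuN+ cells; unusable FOV")
    neun = _clamp_corrected(m.neun_intensity, m.background, f"FOV {m.fov_id} NeuN")
    med = float(np.median(neun))
    if med <= 0:
        raise ValueError(
            f"FOV {m.fov_id}: non-positive NeuN median after background correction"
        )
    ab = _clamp_corrected(m.abjgc_intensity, m.background, f"FOV {m.fov_id} abJGC")
    return ab / med


def kv_expression_ratio(m: KvMeasurement, bg: float = 0.0) -> float:
    """Relative Kv1.2 level: (soma - bg) / (neuropil - bg)."""
    den = m.neuropil_intensity - bg
    if den <= 0:
        raise ValueError(
            f"cell {m.cell_id}: non-positive neuropil intensity after background"
        )
    num = m.soma_intensity - bg
    if num < 0:
        warnings.warn(f"cell {m.cell_id}: soma below background, clamping to 0",
                      stacklevel=2)
        num = 0.0
    return float(num / den)


def pcreb_table(measurements: list[IFMeasurement]) -> pd.DataFrame:
    """Per-cell relative pCREB levels across FOVs as a tidy table."""
    rows = []
    for m in measurements:
        rel = relative_pcreb(m)
        for i, v in enumerate(rel):
            rows.append({"fov_id": m.fov_id, "cell_index": i, "relative_pcreb": v})
    return pd.DataFrame(rows)
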