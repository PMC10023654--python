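"""Cell survival scoring between two imaging sessions.

A census is the set of soma positions in one 635 x 635 x 200 um field of view
at one timepoint.  Cells inside a 100-um XY safety margin are excluded (they
may migrate out of view); a cell survives when its soma is found at the same
position in both sessions, tolerating an offset of <= 4 um (the microscope's
resolution limit).  Matching is a one-to-one optimal assignment so that
near-neighbour ambiguities resolve deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FOVCensus",
    "SurvivalResult",
    "apply_margin",
    "match_survivors",
    "read_census_csv",
    "write_census_csv",
]

DEFAULT_FOV_UM = (635.0, 635.0, 200.0)
DEFAULT_MARGIN_UM = 100.0
MATCH_TOL_UM = 4.0


@dataclass
class FOVCensus:
    """Cell ids and 3-D positions in one field of view at one session."""

    session: str
    cell_ids: np.ndarray
    xyz_um: np.ndarray
    fov_um: tuple[float, float, float] = DEFAULT_FOV_UM
    margin_um: float = DEFAULT_MARGIN_UM
    mouse_id: str = ""

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.xyz_um = np.asarray(self.xyz_um, dtype=float).reshape(-1, 3)
        if len(self.cell_ids) != len(self.xyz_um):
            raise ValueError("cell_ids and xyz_um length mismatch")
        if self.margin_um >= min(self.fov_um[0], self.fov_um[1]) / 2:
            raise ValueError("margin must be below half the FOV extent")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "x_um": self.xyz_um[:, 0],
                "y_um": self.xyz_um[:, 1],
                "z_um": self.xyz_um[:, 2],
            }
        )


@dataclass
class SurvivalResult:
    pairs: pd.DataFrame  # cell_id_a, cell_id_b, distance_um
    survivor_ids: np.ndarray
    survival_rate: float
    n_session_a: int
    n_session_b: int
    excluded_margin_a: int = 0
    excluded_margin_b: int = 0


def apply_margin(census: FOVCensus) -> FOVCensus:
    """Drop cells inside the XY safety margin (boundary inclusive: a cell at
    exactly margin_um is retained).  Z is unrestricted."""
    m = census.margin_um
    fx, fy, _ = census.fov_um
    x, y = census.xyz_um[:, 0], census.xyz_um[:, 1]
    keep = (x >= m) & (x <= fx - m) & (y >= m) & (y <= fy - m)
    return FOVCensus(
        session=census.session,
        cell_ids=census.cell_ids[keep],
        xyz_um=census.xyz_um[keep],
        fov_um=census.fov_um,
        margin_um=census.margin_um,
        mouse_id=census.mouse_id,
    )


def match_survivors(
    a: FOVCensus,
    b: FOVCensus,
    tol_um: float = MATCH_TOL_UM,
    use_z: bool = True,
    margin_filtered: bool = False,
) -> SurvivalResult:
    """Score survival from session a to session b.

    Both censuses are margin-filtered first (skip with
    ``margin_filtered=True`` if already done), then matched one-to-one by
    minimising total displacement; pairs farther than ``tol_um`` apart are
    rejected (boundary inclusive: an offset of exactly 4 um survives).  The
    survival rate is matched cells over retained session-a cells.
    """
    if not margin_filtered:
        n_a0, n_b0 = a.n_cells, b.n_cells
        a, b = apply_margin(a), apply_margin(b)
        excl_a, excl_b = n_a0 - a.n_cells, n_b0 - b.n_cells
    else:
        excl_a = excl_b = 0
    if a.n_cells == 0:
        raise ValueError("empty session-a census after margin filtering")

    dims = slice(None) if use_z else slice(0, 2)
    pa = a.xyz_um[:, dims]
    pb = b.xyz_um[:, dims]
    pairs = pd.DataFrame(columns=["cell_id_a", "cell_id_b", "distance_um"])
    if b.n_cells > 0:
        dist = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        # forbid out-of-gate pairs in the assignment by a large finite cost
        big = tol_um + 1e6
        cost = np.where(dist <= tol_um, dist, big)
        ri, ci = linear_sum_assignment(cost)
        ok = dist[ri, ci] <= tol_um
        pairs = pd.DataFrame(
            {
                "cell_id_a": a.cell_ids[ri[ok]],
                "cell_id_b": b.cell_ids[ci[ok]],
                "distance_um": dist[ri, ci][ok],
            }
        )
    survivors = pairs["cell_id_a"].to_numpy()
    return SurvivalResult(
        pairs=pairs,
        survivor_ids=survivors,
        survival_rate=len(survivors) / a.n_cells,
        n_session_a=a.n_cells,
        n_session_b=b.n_cells,
        excluded_margin_a=excl_a,
        excluded_margin_b=excl_b,
    )


def read_census_csv(csv_path, fov_json_path=None, session: str = "") -> FOVCensus:
    """Census CSV (cell_id, x_um, y_um, z_um) with optional FOV-geometry JSON
    ({"fov_um": [x, y, z], "margin_um": m, "session": s})."""
    df = pd.read_csv(csv_path)
    fov, margin = DEFAULT_FOV_UM, DEFAULT_MARGIN_UM
    if fov_json_path is not None:
        with open(fov_json_path) as fh:
            meta = json.load(fh)
        fov = tuple(meta.get("fov_um", DEFAULT_FOV_UM))
        margin = float(meta.get("margin_um", DEFAULT_MARGIN_UM))
        session = meta.get("session", session)
    return FOVCensus(
        session=session,
        cell_ids=df["cell_id"].to_numpy(),
        xyz_um=df[["x_um", "y_um", "z_um"]].to_numpy(),
        fov_um=fov,
        margin_um=margin,
    )


def write_census_csv(census: FOVCensus, csv_path, fov_json_path=None) -> None:
    census.to_frame().to_csv(csv_path, index=False)
    if fov_json_path is not None:
        with open(fov_json_path, "w") as fh:
            json.dump(
                {"fov_um": list(census.fov_um), "margin_um": census.margin_um,
                 "session": census.session},
                fh,
            )
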