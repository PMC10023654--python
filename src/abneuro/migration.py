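"""Migration metrics for 3-D soma trajectories.

Within a session a cell is tracked every 15 min for 4 h; the per-interval
migration distance is the Euclidean 3-D displacement D = sqrt(dX^2 + dY^2 +
dZ^2), speed is D normalized to a 15-min interval, and a cell counts as
moving when any interval displacement exceeds 4 um (the axial resolution
limit of the 2-um-step stacks).  Across sessions the same 4-um gate flags
long-term migration between matched censuses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellTrack",
    "MigrationMetrics",
    "step_distance",
    "classify_moving",
    "speed_metrics",
    "longterm_motility",
    "read_tracks_csv",
    "write_tracks_csv",
]

MOVING_THRESHOLD_UM = 4.0
NOMINAL_INTERVAL_MIN = 15.0


@dataclass
class CellTrack:
    """Time-ordered 3-D soma positions of one cell within a session."""

    cell_id: str
    t_min: np.ndarray
    xyz_um: np.ndarray  # (n, 3)
    mouse_id: str = ""
    group: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.xyz_um = np.asarray(self.xyz_um, dtype=float)
        if self.xyz_um.ndim != 2 or self.xyz_um.shape[1] != 3:
            raise ValueError("xyz_um must be (n, 3)")
        if len(self.t_min) != len(self.xyz_um):
            raise ValueError("t_min and xyz_um length mismatch")
        if len(self.t_min) >= 2 and not np.all(np.diff(self.t_min) > 0):
            raise ValueError(f"non-monotone timestamps for cell {self.cell_id}")
        if not np.all(np.isfinite(self.xyz_um)):
            raise ValueError("non-finite coordinates")


@dataclass
class MigrationMetrics:
    cell_id: str
    distances_um: np.ndarray
    speeds_um_per_15min: np.ndarray
    median_speed: float
    max_speed: float
    translocation_4h_um: float
    moving: bool
    interval_moving: np.ndarray


def step_distance(p0, p1) -> float:
    """Euclidean 3-D migration distance between two soma positions (um)."""
    d = np.asarray(p1, dtype=float) - np.asarray(p0, dtype=float)
    return float(np.linalg.norm(d))


def classify_moving(
    track: CellTrack, threshold_um: float = MOVING_THRESHOLD_UM
) -> tuple[bool, np.ndarray]:
    """Moving iff any consecutive-interval displacement is strictly > 4 um."""
    if len(track.t_min) < 2:
        raise ValueError(f"track {track.cell_id} has a single position")
    d = np.linalg.norm(np.diff(track.xyz_um, axis=0), axis=1)
    flags = d > threshold_um
    return bool(flags.any()), flags


def speed_metrics(
    track: CellTrack, threshold_um: float = MOVING_THRESHOLD_UM
) -> MigrationMetrics:
    """Per-interval distances and speeds normalized to um per 15 min.

    Speeds use the actual inter-stack time, so a skipped stack (30-min gap)
    contributes D / 2 in the 15-min unit.  The 4-h translocation is the net
    first-to-last displacement.
    """
    if len(track.t_min) < 2:
        raise ValueError(f"track {track.cell_id} has a single position")
    d = np.linalg.norm(np.diff(track.xyz_um, axis=0), axis=1)
    dt = np.diff(track.t_min)
    speeds = d / (dt / NOMINAL_INTERVAL_MIN)
    moving, flags = classify_moving(track, threshold_um)
    return MigrationMetrics(
        cell_id=track.cell_id,
        distances_um=d,
        speeds_um_per_15min=speeds,
        median_speed=float(np.median(speeds)),
        max_speed=float(speeds.max()),
        translocation_4h_um=step_distance(track.xyz_um[0], track.xyz_um[-1]),
        moving=moving,
        interval_moving=flags,
    )


def longterm_motility(
    census_a, census_b, gate_um: float = MOVING_THRESHOLD_UM
) -> pd.DataFrame:
    """Flag cells that changed position between two sessions (shared ids).

    A cell migrated when its inter-session displacement is strictly greater
    than ``gate_um``.  Cells present in only one census are excluded and
    counted in the ``matched`` column.  Input censuses are
    :class:`abneuro.survival.FOVCensus` objects or DataFrames with columns
    cell_id, x_um, y_um, z_um.
    """
    df_a = _census_frame(census_a).set_index("cell_id")
    df_b = _census_frame(census_b).set_index("cell_id")
    shared = df_a.index.intersection(df_b.index)
    rows = []
    for cid in df_a.index:
        if cid in shared:
            disp = step_distance(
                df_a.loc[cid, ["x_um", "y_um", "z_um"]].to_numpy(),
                df_b.loc[cid, ["x_um", "y_um", "z_um"]].to_numpy(),
            )
            rows.append(
                {"cell_id": cid, "matched": True, "displacement_um": disp,
                 "migrated": disp > gate_um}
            )
        else:
            rows.append(
                {"cell_id": cid, "matched": False, "displacement_um": np.nan,
                 "migrated": pd.NA}
            )
    return pd.DataFrame(rows)


def _census_frame(c) -> pd.DataFrame:
    if isinstance(c, pd.DataFrame):
        return c
    return c.to_frame()  # FOVCensus


TRACK_COLUMNS = ["cell_id", "session", "t_min", "x_um", "y_um", "z_um"]


def read_tracks_csv(path) -> list[CellTrack]:
    """Read per-cell tracks from a long-format CSV (one row per time point)."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    tracks = []
    for (cid, sess), g in df.groupby(["cell_id", "session"], sort=True):
        g = g.sort_values("t_min")
        tracks.append(
            CellTrack(
                cell_id=str(cid),
                session=str(sess),
                t_min=g["t_min"].to_numpy(),
                xyz_um=g[["x_um", "y_um", "z_um"]].to_numpy(),
                mouse_id=str(g["mouse_id"].iloc[0]) if "mouse_id" in g else "",
                group=str(g["group"].iloc[0]) if "group" in g else "",
            )
        )
    return tracks


def write_tracks_csv(tracks: list[CellTrack], path) -> None:
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "session": tr.session,
                    "t_min": tr.t_min,
                    "x_um": tr.xyz_um[:, 0],
                    "y_um": tr.xyz_um[:, 1],
                    "z_um": tr.xyz_um[:, 2],
                    "mouse_id": tr.mouse_id,
                    "group": tr.group,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
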