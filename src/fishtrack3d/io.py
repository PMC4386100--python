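"""Plain-text file formats: trajectory CSV, detections CSV, endpoint TSV.

Every table is UTF-8 with a header row and '.' decimal separator; all
readers round-trip the writers bit-for-bit at 1e-9 precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import Trajectory3D, ValidationError
from .optics import DualViewDetections

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_detections",
    "read_detections",
    "write_endpoint_table",
    "read_endpoint_table",
]

_TRAJ_COLUMNS = ["time_s", "fish_id", "x_mm", "y_mm", "z_mm"]
_DET_COLUMNS = ["time_s", "fish_id", "view", "u_px", "v_px"]


def write_trajectories(trajectories: Iterable[Trajectory3D],
                       path: str | Path) -> None:
    """One row per sample; frames with missing positions are omitted."""
    frames = []
    for traj in trajectories:
        m = traj.valid_mask
        frames.append(pd.DataFrame({
            "time_s": traj.times_s[m],
            "fish_id": traj.fish_id,
            "x_mm": traj.positions_mm[m, 0],
            "y_mm": traj.positions_mm[m, 1],
            "z_mm": traj.positions_mm[m, 2],
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_TRAJ_COLUMNS))
    df.to_csv(path, index=False, float_format="%.9g")


def read_trajectories(path: str | Path) -> list[Trajectory3D]:
    """Read a trajectory CSV into one :class:`Trajectory3D` per fish.

    Rows are sorted by time within each fish; duplicated or non-monotonic
    timestamps raise an error naming the fish and the first offending
    (1-based, header-inclusive) line; unknown columns only warn.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in _TRAJ_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return []

    df["_line"] = np.arange(2, len(df) + 2)  # line numbers incl. header
    out: list[Trajectory3D] = []
    for fish_id, sub in df.groupby("fish_id", sort=True):
        sub = sub.sort_values("time_s", kind="stable")
        dup = np.flatnonzero(np.diff(sub["time_s"].to_numpy()) <= 0)
        if dup.size:
            line = int(sub["_line"].iloc[dup[0] + 1])
            raise ValidationError(
                f"{path}: non-increasing timestamp for fish {fish_id!r} "
                f"at line {line}"
            )
        out.append(Trajectory3D(
            fish_id=str(fish_id),
            times_s=sub["time_s"].to_numpy(dtype=float),
            positions_mm=sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        ))
    return out


def write_detections(detections: Iterable[DualViewDetections],
                     path: str | Path) -> None:
    """Long-format detections CSV; missing detections are absent rows."""
    frames = []
    for det in detections:
        for view, uv in (("front", det.front_uv_px), ("top", det.top_uv_px)):
            m = np.all(np.isfinite(uv), axis=1)
            frames.append(pd.DataFrame({
                "time_s": det.times_s[m],
                "fish_id": det.fish_id,
                "view": view,
                "u_px": uv[m, 0],
                "v_px": uv[m, 1],
            }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_DET_COLUMNS))
    df.to_csv(path, index=False, float_format="%.9g")


def read_detections(path: str | Path) -> list[DualViewDetections]:
    """Read a detections CSV into one :class:`DualViewDetections` per fish.

    The per-fish timestamp grid is the union of the times seen in either
    view; a view missing at a grid time becomes a NaN row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _DET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    bad_views = set(df["view"].unique()) - {"front", "top"}
    if bad_views:
        raise ValidationError(f"{path}: unknown view labels {sorted(bad_views)}")

    out: list[DualViewDetections] = []
    for fish_id, sub in df.groupby("fish_id", sort=True):
        times = np.unique(sub["time_s"].to_numpy(dtype=float))
        uv = {v: np.full((times.size, 2), np.nan) for v in ("front", "top")}
        for view, vsub in sub.groupby("view"):
            t = vsub["time_s"].to_numpy(dtype=float)
            if np.unique(t).size != t.size:
                raise ValidationError(
                    f"{path}: duplicate timestamps for fish {fish_id!r} "
                    f"view {view!r}")
            idx = np.searchsorted(times, t)
            uv[view][idx, 0] = vsub["u_px"].to_numpy(dtype=float)
            uv[view][idx, 1] = vsub["v_px"].to_numpy(dtype=float)
        out.append(DualViewDetections(
            fish_id=str(fish_id), times_s=times,
            front_uv_px=uv["front"], top_uv_px=uv["top"],
        ))
    return out


def write_endpoint_table(table: pd.DataFrame, path: str | Path) -> None:
    """Per-pair endpoint TSV (one row per fish pair)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_endpoint_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("group", "pair_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    return df
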