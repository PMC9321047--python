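"""Reading, validating and writing the tabular inputs of the pipeline.

All files are comma-separated UTF-8 with a header row, the dialect produced
by manual-tracking spreadsheet exports:

* trajectory files — one row per ``(focus_id, frame)`` with 3D coordinates
  in μm and optional per-frame focus extents (for ellipsoid volumes);
* cell-edge files — membrane edge coordinates and/or diameter
  measurements per cell;
* per-cell aggregate counts and plate (colony) counts.

Frames are 0-based; times are seconds.  A missing frame is encoded as an
absent row and reconstructed as an explicit gap (a NaN position row) when
the file is read — a gap is never a zero coordinate.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Default frame interval in seconds (time-lapse images every 10 s).
DEFAULT_FRAME_INTERVAL = 10.0

#: Default column names for trajectory files.
DEFAULT_COLUMNS: dict[str, str] = {
    "focus_id": "focus_id",
    "cell_id": "cell_id",
    "frame": "frame",
    "time": "time_s",
    "x": "x_um",
    "y": "y_um",
    "z": "z_um",
    "len_x": "len_x_um",
    "len_y": "len_y_um",
    "len_z": "len_z_um",
    "label": "label",
}


@dataclass
class Trajectory:
    """Time-ordered 3D positions of one tracked focus.

    Parameters
    ----------
    focus_id, cell_id
        Identifiers of the focus and the cell housing it.
    times
        Strictly increasing time stamps in seconds, one per frame.
    positions
        ``(n, 3)`` array of coordinates in μm.  A gap (missing frame) is a
        row of NaN; rows must be either fully observed or fully missing.
    extents
        Optional ``(n, 3)`` per-frame axis lengths (full extents, μm) of
        the focus, used for ellipsoid volumes.  NaN rows where unmeasured.
    label
        Free-text group tag (e.g. strain or size class).
    """

    focus_id: str
    cell_id: str
    times: np.ndarray
    positions: np.ndarray
    extents: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if self.positions.shape != (self.times.size, 3):
            raise ValidationError(
                f"positions must be (n, 3) with n = len(times); got "
                f"{self.positions.shape} for {self.times.size} times"
            )
        if not np.all(np.isfinite(self.times)):
            raise ValidationError("times must be finite")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"times must be strictly increasing (focus {self.focus_id!r})"
            )
        finite = np.isfinite(self.positions)
        mixed = np.any(finite, axis=1) & ~np.all(finite, axis=1)
        if np.any(mixed):
            raise ValidationError(
                "a frame must be fully observed or fully missing; rows "
                f"{np.nonzero(mixed)[0].tolist()} are partially NaN"
            )
        if self.extents is not None:
            self.extents = np.asarray(self.extents, dtype=float)
            if self.extents.shape != self.positions.shape:
                raise ValidationError("extents must match positions in shape")
            with np.errstate(invalid="ignore"):
                if np.any(self.extents <= 0):
                    raise ValidationError("extents must be positive where present")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of frames with a recorded position."""
        return np.all(np.isfinite(self.positions), axis=1)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def n_gaps(self) -> int:
        return self.n_frames - self.n_observed

    def segments(self) -> list[slice]:
        """Maximal runs of consecutive observed frames, as slices."""
        obs = self.observed
        out: list[slice] = []
        start = None
        for i, o in enumerate(obs):
            if o and start is None:
                start = i
            elif not o and start is not None:
                out.append(slice(start, i))
                start = None
        if start is not None:
            out.append(slice(start, obs.size))
        return out

    def mean_volume(self) -> float:
        """Mean ellipsoid volume (μm³) over frames with measured extents.

        Returns NaN if no extents are available.
        """
        if self.extents is None:
            return float("nan")
        from .cell_geometry import ellipsoid_volume

        rows = self.extents[np.all(np.isfinite(self.extents), axis=1)]
        if rows.size == 0:
            return float("nan")
        return float(np.mean([ellipsoid_volume(*row) for row in rows]))


@dataclass
class CellEdgeSet:
    """Membrane measurements of one cell: edge coordinates and/or diameters."""

    cell_id: str
    edge_points: np.ndarray | None = None  # (m, 3) μm
    diameters: np.ndarray | None = None  # (k,) μm

    def __post_init__(self) -> None:
        if self.edge_points is None and self.diameters is None:
            raise ValidationError(
                f"cell {self.cell_id!r}: need edge points or diameters"
            )
        if self.edge_points is not None:
            self.edge_points = np.asarray(self.edge_points, dtype=float)
            if self.edge_points.ndim != 2 or self.edge_points.shape[1] != 3:
                raise ValidationError("edge_points must be (m, 3)")
            if not np.all(np.isfinite(self.edge_points)):
                raise ValidationError("edge_points must be finite")
        if self.diameters is not None:
            self.diameters = np.atleast_1d(np.asarray(self.diameters, dtype=float))
            if np.any(~np.isfinite(self.diameters)) or np.any(self.diameters <= 0):
                raise ValidationError("diameters must be finite and positive")


@dataclass
class CountTable:
    """Per-cell aggregate counts keyed by cell id and group label."""

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("cell_id", "group", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"count table missing column(s): {missing}")
        if len(self.data) == 0:
            raise ValidationError("count table is empty")
        counts = self.data["count"].to_numpy()
        if np.any(counts < 0) or np.any(counts != np.floor(counts)):
            raise ValidationError("counts must be nonnegative integers")

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].astype(str).unique())

    def group_counts(self, group: str) -> np.ndarray:
        sub = self.data[self.data["group"].astype(str) == str(group)]
        if len(sub) == 0:
            raise ValidationError(f"no cells in group {group!r}")
        return sub["count"].to_numpy(dtype=int)


def _resolve(columns: Iterable[str], colmap: Mapping[str, str], key: str) -> str | None:
    name = colmap.get(key, DEFAULT_COLUMNS.get(key))
    return name if name in columns else None


def read_trajectories(
    path: str | Path,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    column_map: Mapping[str, str] | None = None,
    z_scale: float | None = None,
) -> list[Trajectory]:
    """Read a trajectory CSV into one :class:`Trajectory` per focus.

    Rows are keyed by ``(focus_id, frame)``; missing frames become gaps on
    a common 0-based frame grid spanning the file, so a focus first seen at
    frame 30 of a 100-frame movie carries 30 leading gaps.  If the file has
    a time column instead of frames, times are taken verbatim and no gap
    reconstruction is attempted.  ``z_scale`` multiplies the z column
    (stack index × step size is the caller's responsibility; axial step
    sizes vary per movie).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(column_map or {})
    df = pd.read_csv(path)

    id_col = _resolve(df.columns, colmap, "focus_id")
    if id_col is None:
        raise FormatError(f"missing required column {colmap.get('focus_id', DEFAULT_COLUMNS['focus_id'])!r}")
    frame_col = _resolve(df.columns, colmap, "frame")
    time_col = _resolve(df.columns, colmap, "time")
    if frame_col is None and time_col is None:
        raise FormatError("missing frame/time column: need 'frame' or 'time_s'")
    coord_cols = []
    for key in ("x", "y", "z"):
        col = _resolve(df.columns, colmap, key)
        if col is None:
            raise FormatError(
                f"missing required column {colmap.get(key, DEFAULT_COLUMNS[key])!r}"
            )
        coord_cols.append(col)
    cell_col = _resolve(df.columns, colmap, "cell_id")
    label_col = _resolve(df.columns, colmap, "label")
    extent_cols = [_resolve(df.columns, colmap, k) for k in ("len_x", "len_y", "len_z")]
    have_extents = all(c is not None for c in extent_cols)

    if z_scale is not None:
        df = df.copy()
        df[coord_cols[2]] = df[coord_cols[2]] * float(z_scale)

    key_col = frame_col if frame_col is not None else time_col
    dup = df.duplicated(subset=[id_col, key_col])
    if dup.any():
        bad = df.loc[dup, [id_col, key_col]].iloc[0].tolist()
        raise ValidationError(f"duplicate (focus_id, frame/time) entry: {bad}")

    trajectories: list[Trajectory] = []
    if frame_col is not None:
        frames_all = df[frame_col].to_numpy()
        if np.any(frames_all < 0) or np.any(frames_all != np.floor(frames_all)):
            raise ValidationError("frame indices must be nonnegative integers")
        n_frames = int(frames_all.max()) + 1
        grid_times = np.arange(n_frames, dtype=float) * float(frame_interval)
        for focus_id, sub in df.groupby(id_col, sort=True):
            pos = np.full((n_frames, 3), np.nan)
            ext = np.full((n_frames, 3), np.nan) if have_extents else None
            idx = sub[frame_col].to_numpy(dtype=int)
            pos[idx] = sub[coord_cols].to_numpy(dtype=float)
            if ext is not None:
                ext[idx] = sub[extent_cols].to_numpy(dtype=float)
                if not np.any(np.isfinite(ext)):
                    ext = None
            trajectories.append(
                Trajectory(
                    focus_id=str(focus_id),
                    cell_id=str(sub[cell_col].iloc[0]) if cell_col else "",
                    times=grid_times,
                    positions=pos,
                    extents=ext,
                    label=str(sub[label_col].iloc[0]) if label_col else "",
                )
            )
    else:
        for focus_id, sub in df.groupby(id_col, sort=True):
            sub = sub.sort_values(time_col)
            ext = sub[extent_cols].to_numpy(dtype=float) if have_extents else None
            trajectories.append(
                Trajectory(
                    focus_id=str(focus_id),
                    cell_id=str(sub[cell_col].iloc[0]) if cell_col else "",
                    times=sub[time_col].to_numpy(dtype=float),
                    positions=sub[coord_cols].to_numpy(dtype=float),
                    extents=ext,
                    label=str(sub[label_col].iloc[0]) if label_col else "",
                )
            )
    return trajectories


def write_trajectories(path: str | Path, trajectories: Sequence[Trajectory]) -> None:
    """Write trajectories as one CSV row per observed ``(focus, frame)``.

    Gaps are absent rows and survive a round-trip through
    :func:`read_trajectories` (except gaps trailing the last observed
    frame of the whole file, which leave no trace in the frame grid).
    """
    rows = []
    for traj in trajectories:
        obs = np.nonzero(traj.observed)[0]
        for i in obs:
            row = {
                "focus_id": traj.focus_id,
                "cell_id": traj.cell_id,
                "frame": int(i),
                "x_um": traj.positions[i, 0],
                "y_um": traj.positions[i, 1],
                "z_um": traj.positions[i, 2],
            }
            if traj.extents is not None and np.all(np.isfinite(traj.extents[i])):
                row["len_x_um"] = traj.extents[i, 0]
                row["len_y_um"] = traj.extents[i, 1]
                row["len_z_um"] = traj.extents[i, 2]
            row["label"] = traj.label
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cell_edges(path: str | Path) -> list[CellEdgeSet]:
    """Read a cell-edge CSV: either (cell_id, x_um, y_um, z_um) membrane
    coordinates or (cell_id, diameter_um) diameter measurements."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise FormatError("missing required column 'cell_id'")
    out: list[CellEdgeSet] = []
    if {"x_um", "y_um", "z_um"}.issubset(df.columns):
        for cell_id, sub in df.groupby("cell_id", sort=True):
            out.append(
                CellEdgeSet(
                    cell_id=str(cell_id),
                    edge_points=sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                )
            )
    elif "diameter_um" in df.columns:
        for cell_id, sub in df.groupby("cell_id", sort=True):
            out.append(
                CellEdgeSet(
                    cell_id=str(cell_id),
                    diameters=sub["diameter_um"].to_numpy(dtype=float),
                )
            )
    else:
        raise FormatError(
            "edge file needs columns (x_um, y_um, z_um) or 'diameter_um'"
        )
    return out


def write_cell_edges(path: str | Path, edges: Sequence[CellEdgeSet]) -> None:
    rows = []
    for e in edges:
        if e.edge_points is not None:
            for p in e.edge_points:
                rows.append(
                    {"cell_id": e.cell_id, "x_um": p[0], "y_um": p[1], "z_um": p[2]}
                )
        else:
            for d in e.diameters:
                rows.append({"cell_id": e.cell_id, "diameter_um": d})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_counts(path: str | Path) -> CountTable:
    """Read a per-cell aggregate count CSV (cell_id, group, count)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "group" not in df.columns:
        df = df.assign(group="")
    return CountTable(df)


def read_plate_counts(path: str | Path) -> pd.DataFrame:
    """Read plate counts (group, colonies_selective, cfu_total[, density_factor])."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in ("colonies_selective", "cfu_total") if c not in df.columns]
    if missing:
        raise FormatError(f"plate count file missing column(s): {missing}")
    if "density_factor" not in df.columns:
        df = df.assign(density_factor=100.0)
    return df


def write_results(
    path: str | Path,
    records: Sequence,
    fields: Sequence[str] | None = None,
) -> None:
    """Write a sequence of dataclass instances or mappings to CSV.

    Values round-trip through :func:`read_results` at full float precision.
    An empty record list yields a header-only file (a warning is logged);
    pass ``fields`` to control its header.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"directory does not exist: {path.parent}")
    if len(records) == 0:
        logger.warning("write_results: empty record list, writing header only")
        pd.DataFrame(columns=list(fields or [])).to_csv(path, index=False)
        return
    rows = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for r in records
    ]
    df = pd.DataFrame(rows)
    if fields is not None:
        df = df[list(fields)]
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)
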