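"""In-memory containers for ROI fluorescence traces and cell positions.

A :class:`TraceSet` holds the cells-by-frames fluorescence matrix together
with the (uniform) frame times; its ``stage`` records how far the signal has
been conditioned (``raw`` -> ``f_over_f0`` -> ``unit``).  A :class:`CellMap`
holds ROI centroid coordinates in micrometres plus a beta/non-beta flag.

File dialects (plain CSV, see ``to_csv``/``from_csv``):

* trace table -- header ``time_s,cell_<id>,...``, one row per frame;
* position table -- header ``cell_id,x_um,y_um,is_beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TraceSet", "CellMap", "STAGES"]

STAGES = ("raw", "f_over_f0", "unit")

# Full-precision float format so CSV round-trips are lossless.
_FLOAT_FMT = "%.17g"

_TIME_TOL = 1e-6  # relative tolerance on frame-interval uniformity


@dataclass
class TraceSet:
    """Fluorescence time series for a set of ROIs.

    Parameters
    ----------
    times : (n_frames,) array
        Frame timestamps in seconds, strictly increasing and uniform.
    values : (n_cells, n_frames) array
        Fluorescence per cell and frame.
    cell_ids : sequence of int
        ROI identifiers, one per row of ``values``.
    stage : {"raw", "f_over_f0", "unit"}
        Conditioning stage of ``values``.
    flags : dict
        Per-cell bookkeeping (e.g. constant traces flagged by unit rescale,
        cells whose bleach fit fell back to linear).
    """

    times: np.ndarray
    values: np.ndarray
    cell_ids: list[int]
    stage: str = "raw"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.cell_ids = [int(c) for c in self.cell_ids]
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.shape != (len(self.cell_ids), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {self.times.size} frames"
            )
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.ptp(dt) > _TIME_TOL * dt.mean():
                raise ValueError("frame times must be uniformly spaced")

    # ---------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def frame_interval_s(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two frames to define a frame interval")
        return float(self.times[1] - self.times[0])

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / self.frame_interval_s

    def copy(self, **changes) -> "TraceSet":
        new = replace(
            self,
            times=self.times.copy(),
            values=self.values.copy(),
            cell_ids=list(self.cell_ids),
            flags=dict(self.flags),
        )
        for k, v in changes.items():
            setattr(new, k, v)
        return new

    # ---------------------------------------------------------------
    def index_of(self, cell_id: int) -> int:
        try:
            return self.cell_ids.index(int(cell_id))
        except ValueError:
            raise KeyError(f"no cell with id {cell_id}") from None

    def select_cells(self, cell_ids: Sequence[int]) -> "TraceSet":
        idx = [self.index_of(c) for c in cell_ids]
        return TraceSet(
            times=self.times.copy(),
            values=self.values[idx].copy(),
            cell_ids=[int(c) for c in cell_ids],
            stage=self.stage,
            flags=dict(self.flags),
        )

    def slice_time(self, t_start_s: float, t_end_s: float) -> "TraceSet":
        """Frames with ``t_start_s <= t < t_end_s`` (half-open)."""
        mask = (self.times >= t_start_s) & (self.times < t_end_s)
        if not mask.any():
            raise ValueError(
                f"time slice [{t_start_s}, {t_end_s}) contains no frames"
            )
        return TraceSet(
            times=self.times[mask],
            values=self.values[:, mask],
            cell_ids=list(self.cell_ids),
            stage=self.stage,
            flags=dict(self.flags),
        )

    # -- I/O ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times})
        for i, cid in enumerate(self.cell_ids):
            df[f"cell_{cid}"] = self.values[i]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_csv(cls, path, stage: str = "raw") -> "TraceSet":
        df = pd.read_csv(path, float_precision="round_trip")
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: trace CSV must have a 'time_s' column")
        cell_cols = [c for c in df.columns if c.startswith("cell_")]
        if not cell_cols:
            raise ValueError(f"{path}: trace CSV has no 'cell_<id>' columns")
        cell_ids = [int(c.split("_", 1)[1]) for c in cell_cols]
        return cls(
            times=df["time_s"].to_numpy(),
            values=df[cell_cols].to_numpy().T,
            cell_ids=cell_ids,
            stage=stage,
        )


@dataclass
class CellMap:
    """ROI centroid positions (µm) and cell-type flags.

    Backed by a DataFrame with columns ``cell_id, x_um, y_um, is_beta``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_id", "x_um", "y_um", "is_beta"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"position table is missing columns: {sorted(missing)}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("duplicate cell ids in position table")
        if not np.isfinite(self.table[["x_um", "y_um"]].to_numpy()).all():
            raise ValueError("cell positions must be finite")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, cell_ids, x_um, y_um, is_beta=None) -> "CellMap":
        n = len(cell_ids)
        if is_beta is None:
            is_beta = np.ones(n, dtype=bool)
        return cls(
            pd.DataFrame(
                {
                    "cell_id": np.asarray(cell_ids, dtype=int),
                    "x_um": np.asarray(x_um, dtype=float),
                    "y_um": np.asarray(y_um, dtype=float),
                    "is_beta": np.asarray(is_beta, dtype=bool),
                }
            )
        )

    @property
    def cell_ids(self) -> list[int]:
        return [int(c) for c in self.table["cell_id"]]

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def positions(self, cell_ids: Sequence[int] | None = None) -> np.ndarray:
        """(n, 2) array of centroid coordinates, optionally reordered."""
        if cell_ids is None:
            return self.table[["x_um", "y_um"]].to_numpy()
        indexed = self.table.set_index("cell_id")
        missing = [c for c in cell_ids if c not in indexed.index]
        if missing:
            raise KeyError(f"position table is missing cell id(s): {missing}")
        return indexed.loc[list(cell_ids), ["x_um", "y_um"]].to_numpy()

    def subset(self, cell_ids: Sequence[int]) -> "CellMap":
        indexed = self.table.set_index("cell_id")
        missing = [c for c in cell_ids if c not in indexed.index]
        if missing:
            raise KeyError(f"position table is missing cell id(s): {missing}")
        sub = indexed.loc[list(cell_ids)].reset_index()
        return CellMap(sub)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_csv(cls, path) -> "CellMap":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            df.astype(
                {c: t for c, t in
                 [("cell_id", int), ("x_um", float), ("y_um", float), ("is_beta", bool)]
                 if c in df.columns}
            )
        )
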