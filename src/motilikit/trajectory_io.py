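"""Reading, validation, calibration, segmentation and writing of trajectories.

A trajectory is one cell's time-ordered sequence of (x, y) positions in
micrometres with time in minutes.  Datasets are delimited-text tables, one
row per (cell, timepoint), accompanied by optional per-condition metadata
(acquisition interval, total duration, pixel size, 2D/3D label).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: default column names of the trajectory table
DEFAULT_SCHEMA = {
    "condition_id": "condition_id",
    "cell_id": "cell_id",
    "t": "t_min",
    "x": "x_um",
    "y": "y_um",
}

_UNIFORM_TOL = 1e-9  # minutes


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A trajectory violates a structural invariant (named in the message)."""


@dataclass
class Trajectory:
    """One cell's time-ordered (x, y, t) samples.

    Parameters
    ----------
    cell_id, condition_id : str
    t : array of minutes, strictly increasing, length >= 2
    x, y : arrays of micrometres, finite
    interval : nominal sampling interval in minutes (uniform spacing when
        ``is_uniform`` is true, else the nominal/median raw interval).
    """

    cell_id: str
    condition_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    interval: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError(f"cell {self.cell_id}: t/x/y length mismatch")
        if len(self.t) < 2:
            raise ValidationError(f"cell {self.cell_id}: fewer than 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"cell {self.cell_id}: timestamps not strictly increasing"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError(f"cell {self.cell_id}: non-finite coordinates")
        if self.interval <= 0:
            raise ValidationError(f"cell {self.cell_id}: non-positive interval")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Elapsed time in minutes."""
        return float(self.t[-1] - self.t[0])

    @property
    def is_uniform(self) -> bool:
        return bool(
            np.all(np.abs(np.diff(self.t) - self.interval) <= _UNIFORM_TOL)
        )

    def displacements(self) -> np.ndarray:
        """Step displacement vectors, shape (n-1, 2)."""
        return np.column_stack([np.diff(self.x), np.diff(self.y)])


@dataclass
class ConditionMetadata:
    """Acquisition settings of one biological condition."""

    condition_id: str
    total_duration: float  # minutes
    acquisition_interval: float  # minutes
    pixel_size: float = 1.0  # um / pixel
    dimensionality: str = "2D"
    description: str = ""

    def __post_init__(self) -> None:
        if self.acquisition_interval <= 0:
            raise ValidationError(
                f"{self.condition_id}: acquisition_interval must be > 0"
            )
        if self.pixel_size <= 0:
            raise ValidationError(f"{self.condition_id}: pixel_size must be > 0")
        if self.total_duration < self.acquisition_interval:
            raise ValidationError(
                f"{self.condition_id}: total_duration < acquisition_interval"
            )
        if self.dimensionality not in ("2D", "3D"):
            raise ValidationError(
                f"{self.condition_id}: dimensionality must be '2D' or '3D'"
            )


@dataclass
class TrajectorySet:
    """A collection of trajectories with per-condition metadata."""

    trajectories: list[Trajectory] = field(default_factory=list)
    metadata: dict[str, ConditionMetadata] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for traj in self.trajectories:
            key = (traj.condition_id, traj.cell_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate cell_id {traj.cell_id!r} in condition "
                    f"{traj.condition_id!r}"
                )
            seen.add(key)
            if self.metadata and traj.condition_id not in self.metadata:
                raise ValidationError(
                    f"condition {traj.condition_id!r} has no metadata"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def conditions(self) -> list[str]:
        return sorted({traj.condition_id for traj in self.trajectories})

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per (cell, timepoint)."""
        parts = [
            pd.DataFrame(
                {
                    "condition_id": traj.condition_id,
                    "cell_id": traj.cell_id,
                    "t_min": traj.t,
                    "x_um": traj.x,
                    "y_um": traj.y,
                }
            )
            for traj in self.trajectories
        ]
        if not parts:
            return pd.DataFrame(
                columns=["condition_id", "cell_id", "t_min", "x_um", "y_um"]
            )
        return pd.concat(parts, ignore_index=True)


def read_metadata(path) -> dict[str, ConditionMetadata]:
    """Read a per-condition metadata CSV keyed by condition_id."""
    df = pd.read_csv(path, dtype={"condition_id": str})
    required = {"condition_id", "total_duration", "acquisition_interval"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"metadata file missing columns: {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        meta = ConditionMetadata(
            condition_id=str(row.condition_id),
            total_duration=float(row.total_duration),
            acquisition_interval=float(row.acquisition_interval),
            pixel_size=float(getattr(row, "pixel_size", 1.0)),
            dimensionality=str(getattr(row, "dimensionality", "2D")),
            description=str(getattr(row, "description", "")),
        )
        out[meta.condition_id] = meta
    return out


def write_metadata(metadata: dict[str, ConditionMetadata], path) -> None:
    rows = [
        {
            "condition_id": m.condition_id,
            "total_duration": m.total_duration,
            "acquisition_interval": m.acquisition_interval,
            "pixel_size": m.pixel_size,
            "dimensionality": m.dimensionality,
            "description": m.description,
        }
        for m in metadata.values()
    ]
    pd.DataFrame(
        rows,
        columns=[
            "condition_id",
            "total_duration",
            "acquisition_interval",
            "pixel_size",
            "dimensionality",
            "description",
        ],
    ).to_csv(path, index=False)


def read_trajectories(
    path,
    schema: dict | None = None,
    metadata_path=None,
    pixel_units: str = "um",
    time_units: str = "min",
    sep: str = ",",
) -> TrajectorySet:
    """Read a delimited trajectory table into a TrajectorySet.

    Rows are grouped by (condition_id, cell_id) and sorted by time, so the
    result is independent of row order.  When ``pixel_units='px'`` coordinates
    are converted to micrometres using each condition's pixel size; when
    ``time_units='frames'`` time is ``frame_index * acquisition_interval``.
    Both conversions require a metadata file.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory table missing columns: {missing}")

    metadata = read_metadata(metadata_path) if metadata_path is not None else {}
    if pixel_units == "px" and not metadata:
        raise SchemaError("pixel_units='px' requires a metadata file")
    if time_units == "frames" and not metadata:
        raise SchemaError("time_units='frames' requires a metadata file")

    trajectories = []
    grouped = df.groupby(
        [colmap["condition_id"], colmap["cell_id"]], sort=True
    )
    for (cond, cell), grp in grouped:
        cond, cell = str(cond), str(cell)
        grp = grp.sort_values(colmap["t"], kind="mergesort")
        t = grp[colmap["t"]].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"cell {cell!r} in condition {cond!r}: duplicate or "
                "non-monotone timestamps"
            )
        x = grp[colmap["x"]].to_numpy(dtype=float)
        y = grp[colmap["y"]].to_numpy(dtype=float)
        meta = metadata.get(cond)
        if time_units == "frames":
            t = t * meta.acquisition_interval
        if pixel_units == "px":
            x = x * meta.pixel_size
            y = y * meta.pixel_size
        interval = (
            meta.acquisition_interval
            if meta is not None
            else float(np.median(np.diff(t)))
        )
        trajectories.append(
            Trajectory(
                cell_id=cell, condition_id=cond, t=t, x=x, y=y,
                interval=interval,
            )
        )
    return TrajectorySet(trajectories=trajectories, metadata=metadata)


def write_dataset(ts: TrajectorySet, path, metadata_path=None) -> None:
    """Write a TrajectorySet as a CSV table (plus optional metadata CSV).

    Round-trips with :func:`read_trajectories` up to float formatting.
    """
    ts.to_frame().to_csv(path, index=False)
    if metadata_path is not None and ts.metadata:
        write_metadata(ts.metadata, metadata_path)


def segment_trajectory(traj: Trajectory, window: float) -> list[Trajectory]:
    """Cut a uniform trajectory into consecutive non-overlapping segments.

    Each segment spans exactly ``window`` minutes of elapsed time
    (``window/interval`` steps, hence ``window/interval + 1`` samples); the
    boundary sample is shared as the next segment's origin so displacement
    continuity is preserved.  A trailing remainder shorter than ``window`` is
    discarded.  Segment times are re-zeroed and ids suffix the cell id.
    """
    if not traj.is_uniform:
        raise ValidationError(f"cell {traj.cell_id}: not uniformly sampled")
    steps = window / traj.interval
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(
            f"window {window} min is not a multiple of the interval "
            f"{traj.interval} min"
        )
    steps = int(round(steps))
    n_segments = int(math.floor((len(traj) - 1) / steps))
    segments = []
    for k in range(n_segments):
        sl = slice(k * steps, k * steps + steps + 1)
        segments.append(
            Trajectory(
                cell_id=f"{traj.cell_id}_T{k + 1}",
                condition_id=traj.condition_id,
                t=traj.t[sl] - traj.t[sl.start],
                x=traj.x[sl],
                y=traj.y[sl],
                interval=traj.interval,
            )
        )
    return segments


def truncate_trajectory(traj: Trajectory, duration: float) -> Trajectory:
    """Keep the leading ``duration`` minutes of a uniform trajectory."""
    if not traj.is_uniform:
        raise ValidationError(f"cell {traj.cell_id}: not uniformly sampled")
    n = int(round(duration / traj.interval)) + 1
    if n > len(traj):
        raise ValueError(
            f"cell {traj.cell_id}: shorter than requested {duration} min"
        )
    return replace(
        traj, t=traj.t[:n] - traj.t[0], x=traj.x[:n], y=traj.y[:n]
    )
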