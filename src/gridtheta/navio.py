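"""Data model and file I/O for trajectories, voxel series and responses.

Conventions (frozen):

* Coordinates: origin at the arena's south-west corner, x east, y north, in
  virtual metres (vm).  Heading 0 degrees = north, increasing clockwise, in
  ``[0, 360)``.
* Time is a shared monotonic clock in seconds; task blocks are concatenated
  on that clock with explicit ``block_id`` labels, never merged.
* Trajectory CSV columns: ``t_s, x_vm, y_vm, heading_deg, moving_bool,
  block_id``.  Behavior CSV columns: ``block, trial, object, phase, true_x,
  true_y, resp_x, resp_y``.  Voxel series live in HDF5 under
  ``/blocks/<block_id>/values`` (voxels x samples) with ``sample_rate`` and
  ``start_time`` attributes and a shared ``/voxel_labels`` dataset.

Readers validate invariants and raise :class:`~gridtheta.errors.FormatError`
naming the offending row instead of silently coercing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, FormatError, InvalidArgumentError

__all__ = [
    "TrajectoryLog",
    "VoxelSeries",
    "AlignedDirection",
    "read_trajectory",
    "write_trajectory",
    "read_voxel_series",
    "write_voxel_series",
    "read_behavior",
    "write_behavior",
    "read_ground_truth",
    "write_ground_truth",
    "align_direction_to_signal",
]

TRAJECTORY_COLUMNS = ["t_s", "x_vm", "y_vm", "heading_deg", "moving_bool", "block_id"]
BEHAVIOR_COLUMNS = ["block", "trial", "object", "phase", "true_x", "true_y", "resp_x", "resp_y"]


@dataclass
class TrajectoryLog:
    """Time-indexed 2-D position, heading and movement state."""

    t: np.ndarray          # s, strictly increasing
    x: np.ndarray          # vm
    y: np.ndarray          # vm
    heading: np.ndarray    # degrees in [0, 360)
    moving: np.ndarray     # bool, True during translational movement
    block_id: np.ndarray   # label per sample

    def __post_init__(self):
        for name in ("t", "x", "y", "heading"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.moving = np.asarray(self.moving, dtype=bool)
        self.block_id = np.asarray(self.block_id)
        self.validate()

    def validate(self):
        n = self.t.size
        for name in ("x", "y", "heading", "moving", "block_id"):
            if getattr(self, name).size != n:
                raise FormatError(f"column {name} length != t length")
        bad = np.nonzero(np.diff(self.t) <= 0)[0]
        if bad.size:
            raise FormatError("non-monotone time", row=int(bad[0]) + 1)
        bad = np.nonzero((self.heading < 0) | (self.heading >= 360))[0]
        if bad.size:
            raise FormatError("heading outside [0, 360)", row=int(bad[0]))
        # uniform sampling within each block, to one sample-period tolerance
        for b in self.blocks():
            sel = self.block_id == b
            tb = self.t[sel]
            if tb.size >= 3:
                dt = np.diff(tb)
                med = np.median(dt)
                if np.max(np.abs(dt - med)) > med + 1e-9:
                    row = int(np.flatnonzero(sel)[np.argmax(np.abs(dt - med)) + 1])
                    raise FormatError("non-uniform sampling within block", row=row)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def blocks(self):
        _, idx = np.unique(self.block_id, return_index=True)
        return [self.block_id[i] for i in sorted(idx)]

    def block(self, block_id) -> "TrajectoryLog":
        sel = self.block_id == block_id
        return TrajectoryLog(self.t[sel], self.x[sel], self.y[sel],
                             self.heading[sel], self.moving[sel], self.block_id[sel])

    @property
    def speed(self) -> np.ndarray:
        """Translational speed (vm/s) by forward difference; 0 when not moving."""
        v = np.zeros_like(self.t)
        dt = np.diff(self.t)
        step = np.hypot(np.diff(self.x), np.diff(self.y))
        v[1:] = step / dt
        return np.where(self.moving, v, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t, "x_vm": self.x, "y_vm": self.y,
            "heading_deg": self.heading, "moving_bool": self.moving.astype(int),
            "block_id": self.block_id,
        })


@dataclass
class VoxelSeries:
    """Continuous multi-voxel signal on a uniform timebase."""

    sample_rate: float           # Hz
    start_time: float            # s, shared clock with TrajectoryLog
    values: np.ndarray           # voxels x samples
    labels: list = field(default_factory=list)
    block_id: str = "0"

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite voxel values")
        if not self.labels:
            self.labels = [f"v{i:03d}" for i in range(self.values.shape[0])]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class AlignedDirection:
    """Movement direction resampled to a signal timebase."""

    direction_deg: np.ndarray  # degrees; meaningful only where valid
    valid: np.ndarray          # bool: sample falls inside a translation bout
    index: np.ndarray          # nearest behavioral sample per signal sample


# ---------------------------------------------------------------------------
# trajectory CSV

def write_trajectory(log: TrajectoryLog, path):
    log.to_dataframe().to_csv(path, index=False)


def read_trajectory(path) -> TrajectoryLog:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    return TrajectoryLog(
        df["t_s"].to_numpy(float), df["x_vm"].to_numpy(float),
        df["y_vm"].to_numpy(float), df["heading_deg"].to_numpy(float),
        df["moving_bool"].to_numpy().astype(bool), df["block_id"].to_numpy(str),
    )


# ---------------------------------------------------------------------------
# voxel HDF5

def write_voxel_series(blocks: dict, path):
    """Write ``{block_id: VoxelSeries}`` to one HDF5 file."""
    blocks = dict(blocks)
    with h5py.File(path, "w") as f:
        labels = next(iter(blocks.values())).labels
        f.create_dataset("voxel_labels", data=np.array(labels, dtype="S"))
        grp = f.create_group("blocks")
        for bid, series in blocks.items():
            g = grp.create_group(str(bid))
            g.create_dataset("values", data=series.values)
            g.attrs["sample_rate"] = series.sample_rate
            g.attrs["start_time"] = series.start_time


def read_voxel_series(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        labels = [s.decode() for s in f["voxel_labels"][()]]
        for bid in f["blocks"]:
            g = f["blocks"][bid]
            out[bid] = VoxelSeries(
                sample_rate=float(g.attrs["sample_rate"]),
                start_time=float(g.attrs["start_time"]),
                values=g["values"][()], labels=labels, block_id=bid,
            )
    return out


# ---------------------------------------------------------------------------
# behavior CSV

def write_behavior(responses: pd.DataFrame, path):
    responses[BEHAVIOR_COLUMNS].to_csv(path, index=False)


def read_behavior(path, arena_side: float | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    if arena_side is not None:
        for cx, cy in (("true_x", "true_y"), ("resp_x", "resp_y")):
            bad = np.nonzero(
                (df[cx] < 0) | (df[cx] > arena_side)
                | (df[cy] < 0) | (df[cy] > arena_side)
            )[0]
            if bad.size:
                raise FormatError(f"{cx[:-2]} location outside arena", row=int(bad[0]))
    return df


# ---------------------------------------------------------------------------
# ground truth YAML

def write_ground_truth(truth: dict, path):
    with open(path, "w") as f:
        yaml.safe_dump(truth, f, sort_keys=True)


def read_ground_truth(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


# ---------------------------------------------------------------------------
# alignment

def align_direction_to_signal(traj: TrajectoryLog, series: VoxelSeries) -> AlignedDirection:
    """Pair each signal sample with the nearest behavioral sample's heading.

    Interpolation is nearest-neighbour on the circle: no angular averaging,
    so a heading step across the 0/360 wrap can never produce intermediate
    values.  Samples whose nearest behavioral sample is not moving are
    flagged invalid.
    """
    ts = series.times
    if ts[-1] < traj.t[0] or ts[0] > traj.t[-1]:
        raise AlignmentError("disjoint time ranges between trajectory and signal")
    idx = np.searchsorted(traj.t, ts)
    idx = np.clip(idx, 1, traj.t.size - 1)
    left = idx - 1
    use_left = (ts - traj.t[left]) <= (traj.t[idx] - ts)
    nearest = np.where(use_left, left, idx)
    direction = traj.heading[nearest]
    valid = traj.moving[nearest].copy()
    # outside the behavioral record entirely -> invalid
    dt = np.median(np.diff(traj.t))
    valid &= (ts >= traj.t[0] - dt) & (ts <= traj.t[-1] + dt)
    return AlignedDirection(direction, valid, nearest)
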