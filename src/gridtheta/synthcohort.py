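"""Synthetic cohort generator with planted ground truth.

Emulates button-driven desktop-VR navigation in a square arena (rotation in
place plus forward translation at a fixed top speed, in discrete movement
bouts separated by immobility) and source-space oscillatory signals: 1/f
noise plus a theta carrier whose amplitude rises linearly over the
``onset_lead`` seconds before each movement bout and, in one designated
voxel, is modulated as ``cos(n (theta - phi))`` by movement direction theta
around a planted grid orientation phi.  Every planted parameter is written
to a ground-truth sidecar so downstream stages can be verified by parameter
recovery.

Signal model during a bout (grid voxel)::

    a(t) = base_amp + movement_gain * m(t) + grid_gain * moving(t) * cos(n (theta(t) - phi))
    x(t) = a(t) * sin(2 pi f t) + noise_amp * eta(t)

with ``m(t)`` the movement indicator including the pre-onset ramp and
``eta`` unit-variance 1/f-shaped noise, independent across voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from . import navio
from .navio import TrajectoryLog, VoxelSeries

__all__ = [
    "ArenaSpec",
    "DurationDist",
    "KinematicsSpec",
    "OscillatorSpec",
    "CohortSpec",
    "Participant",
    "simulate_trajectory",
    "simulate_voxel_series",
    "simulate_behavior",
    "simulate_participant",
    "simulate_cohort",
    "concat_trajectories",
    "mean_error_distance",
]


@dataclass(frozen=True)
class ArenaSpec:
    """Square arena; participants start at the centre facing north."""

    side_length: float = 100.0   # vm
    n_object_locations: int = 16

    def __post_init__(self):
        if self.side_length <= 0:
            raise InvalidArgumentError("side_length must be > 0")
        if self.n_object_locations < 4:
            raise InvalidArgumentError("need >= 4 object locations")

    @property
    def start(self):
        return (self.side_length / 2.0, self.side_length / 2.0)

    def object_locations(self) -> np.ndarray:
        """Candidate object locations on an interior grid (strictly inside)."""
        k = int(np.ceil(np.sqrt(self.n_object_locations)))
        coords = self.side_length * (np.arange(1, k + 1)) / (k + 1)
        xx, yy = np.meshgrid(coords, coords)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        return pts[: self.n_object_locations]


@dataclass(frozen=True)
class DurationDist:
    """Bout/pause duration distribution: fixed or log-normal.

    ``mean`` is the arithmetic mean in seconds; for the log-normal, ``sigma``
    is the SD of log-duration and the location parameter is solved so the
    arithmetic mean matches.
    """

    mean: float
    sigma: float = 0.0
    kind: str = "lognormal"

    def __post_init__(self):
        if self.mean <= 0 or self.sigma < 0:
            raise InvalidArgumentError("durations must be positive")
        if self.kind not in ("fixed", "lognormal"):
            raise InvalidArgumentError(f"unknown duration kind {self.kind!r}")

    def sample(self, rng) -> float:
        if self.kind == "fixed" or self.sigma == 0:
            return self.mean
        mu = np.log(self.mean) - 0.5 * self.sigma**2
        return float(rng.lognormal(mu, self.sigma))


@dataclass(frozen=True)
class KinematicsSpec:
    """Button-scheme kinematics: rotate in place, then translate forward.

    Defaults give bouts averaging ~2.2 s (the reported mean movement
    duration) and pauses long enough that qualifying stationary periods
    arise naturally.
    """

    top_speed: float = 5.0          # vm/s
    accel_time: float = 0.3         # s to reach top speed (rapid)
    turn_speed: float = 90.0        # deg/s during immobility
    bout_duration: DurationDist = field(default_factory=lambda: DurationDist(2.2, 0.35))
    pause_duration: DurationDist = field(default_factory=lambda: DurationDist(2.5, 0.4))
    behavioral_sample_rate: float = 50.0  # Hz

    def __post_init__(self):
        if min(self.top_speed, self.turn_speed, self.behavioral_sample_rate) <= 0:
            raise InvalidArgumentError("rates and speeds must be > 0")
        if self.accel_time < 0:
            raise InvalidArgumentError("accel_time must be >= 0")


@dataclass(frozen=True)
class OscillatorSpec:
    """Per-voxel oscillatory signal parameters."""

    signal_sample_rate: float = 200.0  # Hz
    theta_freq: float = 7.0            # Hz, within the 4-10 Hz band
    base_amp: float = 1.0
    movement_gain: float = 1.0
    onset_lead: float = 0.5            # s the amplitude rise precedes onset
    offset_decay: float = 0.5          # s linear amplitude decay after a bout ends
    grid_gain: float = 0.5
    grid_orientation: float = 0.0      # degrees in [0, 360/grid_symmetry)
    grid_symmetry: int = 6
    noise_exponent: float = 1.0        # 1/f slope
    noise_amp: float = 1.0
    n_voxels: int = 27                 # 3x3x3 toy voxel grid
    grid_voxel_index: int = 13         # centre voxel carries the modulation

    def __post_init__(self):
        if self.signal_sample_rate <= 0:
            raise InvalidArgumentError("signal_sample_rate must be > 0")
        if not (4.0 <= self.theta_freq <= 10.0):
            raise InvalidArgumentError("theta_freq must lie in 4-10 Hz")
        if self.grid_gain < 0 or self.grid_gain > self.movement_gain + self.base_amp:
            raise InvalidArgumentError(
                "grid_gain must satisfy 0 <= grid_gain <= movement_gain + base_amp"
            )
        period = 360.0 / self.grid_symmetry
        if not (0.0 <= self.grid_orientation < period):
            raise InvalidArgumentError(f"grid_orientation outside [0, {period})")
        if not (0 <= self.grid_voxel_index < self.n_voxels):
            raise InvalidArgumentError("grid_voxel_index out of range")
        if self.onset_lead < 0 or self.noise_amp < 0 or self.offset_decay < 0:
            raise InvalidArgumentError("onset_lead, offset_decay and noise_amp must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group synthetic cohort; seeds fully determine the output."""

    n_controls: int = 23
    n_patients: int = 17
    n_blocks: int = 3
    block_duration_s: float = 400.0
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    kinematics: KinematicsSpec = field(default_factory=KinematicsSpec)
    oscillator: OscillatorSpec = field(default_factory=OscillatorSpec)  # control template
    patient_movement_gain: float = 0.6
    patient_grid_gain: float = 0.0
    memory_error_scale_control: float = 8.0    # vm (per-axis Gaussian SD)
    memory_error_scale_patient: float = 12.0
    participant_scale_sigma: float = 0.25      # log-normal spread of per-participant scales
    orientation_mode: str = "per_block"        # "per_block" | "jittered"
    orientation_jitter_deg: float = 5.0        # SD of per-block phi jitter (jittered mode)
    couple_instability_performance: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 2 or self.n_patients < 2:
            raise InvalidArgumentError("group sizes must be >= 2")
        if self.n_blocks < 1 or self.block_duration_s <= 0:
            raise InvalidArgumentError("need n_blocks >= 1 and positive duration")
        if self.orientation_mode not in ("per_block", "jittered"):
            raise InvalidArgumentError(f"unknown orientation_mode {self.orientation_mode!r}")


@dataclass
class Participant:
    pid: str
    group: str                      # "control" | "patient"
    trajectory: TrajectoryLog       # all blocks on the shared clock
    voxels: dict                    # block_id -> VoxelSeries
    behavior: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# trajectory

def _reflect(p: np.ndarray, side: float) -> np.ndarray:
    """Fold unbounded straight-line coordinates into [0, side] by reflection."""
    q = np.mod(p, 2.0 * side)
    return np.where(q > side, 2.0 * side - q, q)


def simulate_trajectory(arena: ArenaSpec, kin: KinematicsSpec, duration: float,
                        seed=None) -> TrajectoryLog:
    """Alternating immobility/translation schedule inside the arena.

    Starts with a pause at the arena centre facing north.  During pauses the
    heading rotates (at ``turn_speed``) toward a uniformly drawn target
    direction for the next bout; during bouts the avatar accelerates
    linearly to ``top_speed`` and travels straight, reflecting off the
    boundary (heading updated to the reflected direction of travel).
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be > 0")
    rng = np.random.default_rng(seed)
    rate = kin.behavioral_sample_rate
    dt = 1.0 / rate
    n = int(round(duration * rate))

    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    moving = np.zeros(n, dtype=bool)

    px, py = arena.start
    h = 0.0  # facing north
    i = 0
    while i < n:
        # ---- pause: rotate toward the next bout direction
        n_pause = max(1, int(round(kin.pause_duration.sample(rng) * rate)))
        n_pause = min(n_pause, n - i)
        target = float(rng.uniform(0.0, 360.0))
        delta = (target - h + 180.0) % 360.0 - 180.0
        k = np.arange(1, n_pause + 1)
        rot = np.sign(delta) * np.minimum(np.abs(delta), kin.turn_speed * dt * k)
        x[i:i + n_pause] = px
        y[i:i + n_pause] = py
        heading[i:i + n_pause] = (h + rot) % 360.0
        i += n_pause
        h = heading[i - 1]
        if i >= n:
            break
        # ---- bout: accelerate to top speed, travel straight, reflect
        n_bout = max(1, int(round(kin.bout_duration.sample(rng) * rate)))
        n_bout = min(n_bout, n - i)
        k = np.arange(1, n_bout + 1)
        if kin.accel_time > 0:
            v = kin.top_speed * np.minimum(1.0, k * dt / kin.accel_time)
        else:
            v = np.full(n_bout, kin.top_speed)
        dist = np.cumsum(v * dt)
        hx = np.sin(np.deg2rad(h))
        hy = np.cos(np.deg2rad(h))
        bx = _reflect(px + hx * dist, arena.side_length)
        by = _reflect(py + hy * dist, arena.side_length)
        x[i:i + n_bout] = bx
        y[i:i + n_bout] = by
        dx = np.diff(np.concatenate([[px], bx]))
        dy = np.diff(np.concatenate([[py], by]))
        heading[i:i + n_bout] = np.rad2deg(np.arctan2(dx, dy)) % 360.0
        moving[i:i + n_bout] = True
        i += n_bout
        px, py = float(bx[-1]), float(by[-1])
        h = float(heading[i - 1])

    return TrajectoryLog(t, x, y, heading, moving, np.zeros(n, dtype=int).astype(str))


def concat_trajectories(logs_and_ids, gap_s: float = 5.0) -> TrajectoryLog:
    """Concatenate per-block logs on one monotone clock with explicit ids."""
    parts = []
    offset = 0.0
    for log, bid in logs_and_ids:
        t = log.t - log.t[0] + offset
        parts.append((t, log.x, log.y, log.heading, log.moving,
                      np.full(log.t.size, str(bid))))
        offset = t[-1] + gap_s
    cols = [np.concatenate([p[i] for p in parts]) for i in range(6)]
    return TrajectoryLog(*cols)


# ---------------------------------------------------------------------------
# voxel signal

def _one_over_f_noise(rng, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shape, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _movement_envelope_factor(moving: np.ndarray, fs: float, onset_lead: float,
                              offset_decay: float = 0.0) -> np.ndarray:
    """Movement indicator with a linear 0->1 ramp over [-onset_lead, 0] before
    each bout and a linear 1->0 decay over ``offset_decay`` s after it ends
    (so the envelope never steps discontinuously)."""
    m = moving.astype(float)
    lead_n = int(round(onset_lead * fs))
    if lead_n > 0:
        starts = np.flatnonzero(moving & ~np.concatenate([[False], moving[:-1]]))
        for s in starts:
            j0 = max(0, s - lead_n)
            if j0 == s:
                continue
            ramp = (np.arange(j0, s) - (s - lead_n)) / lead_n  # 0 -> 1 over the lead
            m[j0:s] = np.maximum(m[j0:s], ramp)
    decay_n = int(round(offset_decay * fs))
    if decay_n > 0:
        ends = np.flatnonzero(~moving & np.concatenate([[False], moving[:-1]]))
        for e in ends:
            j1 = min(m.size, e + decay_n)
            if j1 == e:
                continue
            ramp = 1.0 - (np.arange(e, j1) - e + 1) / decay_n
            m[e:j1] = np.maximum(m[e:j1], ramp)
    return m


def simulate_voxel_series(traj: TrajectoryLog, osc: OscillatorSpec, seed=None) -> VoxelSeries:
    """Generate the multi-voxel signal paired with a (single-block) trajectory.

    All voxels share the theta carrier with movement-gated amplitude; only
    ``grid_voxel_index`` additionally carries the directional modulation.
    Noise is independent across voxels.
    """
    rng = np.random.default_rng(seed)
    fs = osc.signal_sample_rate
    t0 = float(traj.t[0])
    n = int(np.floor((traj.t[-1] - t0) * fs)) + 1
    times = t0 + np.arange(n) / fs

    idx = np.searchsorted(traj.t, times)
    idx = np.clip(idx, 1, traj.t.size - 1)
    use_left = (times - traj.t[idx - 1]) <= (traj.t[idx] - times)
    nearest = np.where(use_left, idx - 1, idx)
    moving = traj.moving[nearest]
    heading = traj.heading[nearest]

    m = _movement_envelope_factor(moving, fs, osc.onset_lead, osc.offset_decay)
    carrier = np.sin(2.0 * np.pi * osc.theta_freq * (times - t0))
    base_env = osc.base_amp + osc.movement_gain * m

    values = np.empty((osc.n_voxels, n))
    for v in range(osc.n_voxels):
        env = base_env
        if v == osc.grid_voxel_index and osc.grid_gain > 0:
            mod = np.cos(np.deg2rad(osc.grid_symmetry
                                    * (heading - osc.grid_orientation)))
            env = env + osc.grid_gain * moving * mod
        if np.any(env < -1e-12):
            raise InvalidArgumentError("amplitude became negative")
        sig = env * carrier
        if osc.noise_amp > 0:
            sig = sig + osc.noise_amp * _one_over_f_noise(rng, n, fs, osc.noise_exponent)
        values[v] = sig
    return VoxelSeries(sample_rate=fs, start_time=t0, values=values,
                       block_id=str(traj.block_id[0]))


# ---------------------------------------------------------------------------
# behavior

def simulate_behavior(arena: ArenaSpec, memory_error_scale: float, n_blocks: int,
                      seed=None) -> pd.DataFrame:
    """Per block: 8 encoding trials (2 per object) and 32 retrieval trials
    (8 per object).  Remembered location = true location + isotropic 2-D
    Gaussian error (per-axis SD ``memory_error_scale``), clipped to the arena.
    """
    if n_blocks < 1:
        raise InvalidArgumentError("n_blocks must be >= 1")
    if memory_error_scale < 0:
        raise InvalidArgumentError("memory_error_scale must be >= 0")
    rng = np.random.default_rng(seed)
    candidates = arena.object_locations()
    rows = []
    for b in range(n_blocks):
        locs = candidates[rng.choice(len(candidates), size=4, replace=False)]
        enc_objects = rng.permutation(np.repeat(np.arange(4), 2))
        for trial, obj in enumerate(enc_objects):
            tx, ty = locs[obj]
            rows.append((b, trial, int(obj), "encoding", tx, ty, tx, ty))
        ret_objects = rng.permutation(np.repeat(np.arange(4), 8))
        for trial, obj in enumerate(ret_objects):
            tx, ty = locs[obj]
            err = rng.normal(0.0, memory_error_scale, size=2) if memory_error_scale > 0 else np.zeros(2)
            rx = float(np.clip(tx + err[0], 0.0, arena.side_length))
            ry = float(np.clip(ty + err[1], 0.0, arena.side_length))
            rows.append((b, trial, int(obj), "retrieval", tx, ty, rx, ry))
    return pd.DataFrame(rows, columns=navio.BEHAVIOR_COLUMNS)


def mean_error_distance(scale: float) -> float:
    """Closed-form mean distance of the 2-D Gaussian error model (unclipped):
    the Rayleigh mean ``scale * sqrt(pi/2)``."""
    return float(scale * np.sqrt(np.pi / 2.0))


# ---------------------------------------------------------------------------
# cohort

def _participant_params(spec: CohortSpec, group: str, rng):
    period = 360.0 / spec.oscillator.grid_symmetry
    if group == "control":
        move_gain = spec.oscillator.movement_gain
        grid_gain = spec.oscillator.grid_gain
        scale0 = spec.memory_error_scale_control
    else:
        move_gain = spec.patient_movement_gain
        grid_gain = spec.patient_grid_gain
        scale0 = spec.memory_error_scale_patient
    base_phi = float(rng.uniform(0.0, period))
    jitter_mult = float(rng.lognormal(0.0, 0.5)) if spec.orientation_mode == "jittered" else 1.0
    jitter = spec.orientation_jitter_deg * jitter_mult
    scale_mult = float(rng.lognormal(-0.5 * spec.participant_scale_sigma**2,
                                     spec.participant_scale_sigma))
    if spec.couple_instability_performance and spec.orientation_mode == "jittered":
        scale_mult *= jitter_mult  # unstable grids <-> larger memory error
    phis = []
    for _ in range(spec.n_blocks):
        if spec.orientation_mode == "per_block":
            phis.append(float(rng.uniform(0.0, period)))
        else:
            phis.append(float((base_phi + rng.normal(0.0, jitter)) % period))
    return dict(movement_gain=move_gain, grid_gain=grid_gain,
                memory_error_scale=scale0 * scale_mult,
                base_phi=base_phi, phi_per_block=phis, jitter_deg=jitter)


def simulate_participant(spec: CohortSpec, group: str, index: int,
                         seed_seq: np.random.SeedSequence) -> Participant:
    """Simulate one participant; the SeedSequence fully determines output."""
    children = seed_seq.spawn(2 + 2 * spec.n_blocks)
    rng = np.random.default_rng(children[0])
    params = _participant_params(spec, group, rng)

    logs, voxels = [], {}
    for b in range(spec.n_blocks):
        bid = f"b{b}"
        traj_b = simulate_trajectory(spec.arena, spec.kinematics,
                                     spec.block_duration_s, children[2 + 2 * b])
        traj_b = TrajectoryLog(traj_b.t, traj_b.x, traj_b.y, traj_b.heading,
                               traj_b.moving, np.full(traj_b.t.size, bid))
        logs.append((traj_b, bid))
    full = concat_trajectories(logs, gap_s=5.0)
    for b in range(spec.n_blocks):
        bid = f"b{b}"
        osc_b = replace(spec.oscillator,
                        movement_gain=params["movement_gain"],
                        grid_gain=params["grid_gain"],
                        grid_orientation=params["phi_per_block"][b])
        voxels[bid] = simulate_voxel_series(full.block(bid), osc_b, children[3 + 2 * b])

    behavior = simulate_behavior(spec.arena, params["memory_error_scale"],
                                 spec.n_blocks, children[1])
    pid = f"sub-{'C' if group == 'control' else 'P'}{index:02d}"
    truth = {
        "pid": pid, "group": group,
        "grid_gain": float(params["grid_gain"]),
        "movement_gain": float(params["movement_gain"]),
        "memory_error_scale": float(params["memory_error_scale"]),
        "base_phi_deg": params["base_phi"],
        "phi_per_block_deg": {f"b{b}": params["phi_per_block"][b]
                              for b in range(spec.n_blocks)},
        "orientation_jitter_deg": float(params["jitter_deg"]),
        "grid_symmetry": spec.oscillator.grid_symmetry,
        "theta_freq": spec.oscillator.theta_freq,
        "grid_voxel_index": spec.oscillator.grid_voxel_index,
    }
    return Participant(pid, group, full, voxels, behavior, truth)


def iter_participants(spec: CohortSpec):
    """Yield all participants of the cohort, seed-deterministically.

    Per-participant seeds are spawned from the master seed by group and
    index, so changing cohort size does not perturb existing participants.
    """
    root = np.random.SeedSequence(spec.seed)
    for gi, (group, n) in enumerate((("control", spec.n_controls),
                                     ("patient", spec.n_patients))):
        for i in range(n):
            child = np.random.SeedSequence(entropy=spec.seed,
                                           spawn_key=(gi, i))
            yield simulate_participant(spec, group, i, child)


def simulate_cohort(spec: CohortSpec, outdir) -> list:
    """Write the cohort to disk, one directory per participant.

    Layout: ``<outdir>/<pid>/{trajectory.csv, voxels.h5, behavior.csv,
    truth.yaml}``.  Returns the list of participant directories.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {outdir}: {e}") from e
    dirs = []
    for p in iter_participants(spec):
        pdir = outdir / p.pid
        pdir.mkdir(exist_ok=True)
        navio.write_trajectory(p.trajectory, pdir / "trajectory.csv")
        navio.write_voxel_series(p.voxels, pdir / "voxels.h5")
        navio.write_behavior(p.behavior, pdir / "behavior.csv")
        navio.write_ground_truth(p.truth, pdir / "truth.yaml")
        dirs.append(pdir)
    return dirs


def read_participant(pdir) -> Participant:
    """Load a participant directory written by :func:`simulate_cohort`."""
    pdir = Path(pdir)
    traj = navio.read_trajectory(pdir / "trajectory.csv")
    voxels = navio.read_voxel_series(pdir / "voxels.h5")
    behavior = navio.read_behavior(pdir / "behavior.csv")
    truth = {}
    if (pdir / "truth.yaml").exists():
        truth = navio.read_ground_truth(pdir / "truth.yaml")
    group = truth.get("group", "unknown")
    return Participant(pdir.name, group, traj, voxels, behavior, truth)
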