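"""Movement-onset and stationary epoch segmentation.

A movement-onset epoch is a [-3, 3] s window around the onset of a
continuous translational movement lasting >= 1 s that was preceded by
>= 1 s of complete immobility (translational speed exactly zero; rotation
is permitted).  A stationary epoch is a [-2.5, 3.5] s window around the
onset of a >= 2 s period without translational movement.  Boundary
durations (exactly 1 s / 2 s) qualify.  Movement and stationary analysis
windows ([-0.5, 0.5] and [0, 1] s respectively) may overlap; overlapping
signal samples are excluded from all analyses.  Epochs whose full window
extends beyond the recorded block are flagged not accepted rather than
zero-padded.  Artefact epochs are removed by an iterative generalized-ESD
outlier test on per-epoch log signal variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import h5py
import numpy as np
from scipy import stats

from .errors import InvalidArgumentError
from .navio import TrajectoryLog, VoxelSeries

__all__ = [
    "EpochSet",
    "MOVEMENT_WINDOW",
    "STATIONARY_WINDOW",
    "MOVEMENT_ANALYSIS_WINDOW",
    "STATIONARY_ANALYSIS_WINDOW",
    "detect_movement_onsets",
    "detect_stationary_onsets",
    "exclude_overlap",
    "reject_outlier_epochs",
    "generalized_esd",
    "save_epochs",
    "load_epochs",
]

logger = logging.getLogger(__name__)

MOVEMENT_WINDOW = (-3.0, 3.0)
STATIONARY_WINDOW = (-2.5, 3.5)
MOVEMENT_ANALYSIS_WINDOW = (-0.5, 0.5)
STATIONARY_ANALYSIS_WINDOW = (0.0, 1.0)

_EPS = 1e-9


@dataclass
class EpochSet:
    """Onset-locked windows with per-epoch accept/reject status."""

    kind: str                  # "movement_onset" | "stationary"
    onsets: np.ndarray         # s, sorted
    window: tuple              # [lo, hi] s relative to onset
    accepted: np.ndarray       # bool per epoch
    block_id: np.ndarray       # label per epoch
    bout_end: np.ndarray = None  # s: end of the defining run (for movement samples)

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        self.block_id = np.asarray(self.block_id)
        if self.bout_end is None:
            self.bout_end = np.full(self.onsets.size, np.nan)
        self.bout_end = np.asarray(self.bout_end, dtype=float)
        if np.any(np.diff(self.onsets) < 0):
            raise InvalidArgumentError("onsets must be sorted")

    def __len__(self):
        return self.onsets.size

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop is exclusive."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def detect_movement_onsets(traj: TrajectoryLog, min_move_s: float = 1.0,
                           min_still_s: float = 1.0,
                           window: tuple = MOVEMENT_WINDOW) -> EpochSet:
    """Onsets of qualifying translation bouts, per block.

    The onset is the first moving sample of each bout lasting
    >= ``min_move_s`` that is preceded by >= ``min_still_s`` of recorded
    immobility.  Bouts at the start of a block (immobility unobserved) do
    not qualify.  Epochs whose window crosses a block edge are flagged
    ``accepted = False``.
    """
    onsets, accepted, blocks, ends = [], [], [], []
    for bid in traj.blocks():
        tb = traj.block(bid)
        dt = 1.0 / tb.sample_rate
        runs = _runs(tb.moving)
        still_by_stop = {e: (e - s) * dt for s, e in _runs(~tb.moving)}
        for s, e in runs:
            if (e - s) * dt + _EPS < min_move_s:
                continue
            prev = still_by_stop.get(s)
            if prev is None or prev + _EPS < min_still_s:
                continue
            onset = tb.t[s]
            end = tb.t[e - 1] + dt
            ok = (onset + window[0] >= tb.t[0] - _EPS) and (
                onset + window[1] <= tb.t[-1] + dt + _EPS)
            onsets.append(onset)
            accepted.append(ok)
            blocks.append(bid)
            ends.append(end)
    order = np.argsort(onsets) if onsets else []
    return EpochSet("movement_onset", np.asarray(onsets)[order], window,
                    np.asarray(accepted, dtype=bool)[order],
                    np.asarray(blocks)[order], np.asarray(ends)[order])


def detect_stationary_onsets(traj: TrajectoryLog, min_still_s: float = 2.0,
                             window: tuple = STATIONARY_WINDOW) -> EpochSet:
    """Onsets of >= ``min_still_s`` immobile runs, per block (inclusive >=)."""
    onsets, accepted, blocks, ends = [], [], [], []
    for bid in traj.blocks():
        tb = traj.block(bid)
        dt = 1.0 / tb.sample_rate
        for s, e in _runs(~tb.moving):
            if (e - s) * dt + _EPS < min_still_s:
                continue
            onset = tb.t[s]
            end = tb.t[e - 1] + dt
            ok = (onset + window[0] >= tb.t[0] - _EPS) and (
                onset + window[1] <= tb.t[-1] + dt + _EPS)
            onsets.append(onset)
            accepted.append(ok)
            blocks.append(bid)
            ends.append(end)
    order = np.argsort(onsets) if onsets else []
    return EpochSet("stationary", np.asarray(onsets)[order], window,
                    np.asarray(accepted, dtype=bool)[order],
                    np.asarray(blocks)[order], np.asarray(ends)[order])


def exclude_overlap(move: EpochSet, stat: EpochSet, times: np.ndarray,
                    move_window: tuple = MOVEMENT_ANALYSIS_WINDOW,
                    stat_window: tuple = STATIONARY_ANALYSIS_WINDOW) -> np.ndarray:
    """Mask of signal samples falling in BOTH analysis-window families.

    Any sample inside a movement-onset analysis window and a stationary
    analysis window simultaneously is excluded from every analysis.
    Returns a boolean exclusion mask over ``times`` for audit.
    """
    times = np.asarray(times, dtype=float)

    def _inside(epochset, window):
        inside = np.zeros(times.size, dtype=bool)
        for onset in epochset.onsets:
            inside |= (times >= onset + window[0] - _EPS) & (
                times <= onset + window[1] + _EPS)
        return inside

    return _inside(move, move_window) & _inside(stat, stat_window)


def generalized_esd(x: np.ndarray, alpha: float = 0.05,
                    max_outliers: int | None = None) -> np.ndarray:
    """Indices flagged by the two-sided generalized ESD test (Rosner 1983)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_outliers is None:
        max_outliers = max(1, n // 5)
    if alpha <= 0 or n < 3:
        return np.array([], dtype=int)
    active = np.arange(n)
    removed = []
    stats_r, lams = [], []
    xs = x.copy()
    for i in range(1, max_outliers + 1):
        m = xs[active].mean()
        sd = xs[active].std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(xs[active] - m)
        j = int(np.argmax(dev))
        stats_r.append(dev[j] / sd)
        ni = active.size
        p = 1.0 - alpha / (2.0 * ni)
        tq = stats.t.ppf(p, ni - 2)
        lams.append((ni - 1) * tq / np.sqrt((ni - 2 + tq**2) * ni))
        removed.append(active[j])
        active = np.delete(active, j)
        if active.size < 3:
            break
    n_out = 0
    for i, (r, lam) in enumerate(zip(stats_r, lams), start=1):
        if r > lam:
            n_out = i
    return np.asarray(removed[:n_out], dtype=int)


def _epoch_log_variance(epochset: EpochSet, series_by_block: dict) -> np.ndarray:
    """Per-epoch summary: log within-epoch signal variance, voxel-averaged."""
    out = np.full(len(epochset), np.nan)
    for i, (onset, bid) in enumerate(zip(epochset.onsets, epochset.block_id)):
        series = series_by_block[str(bid)]
        t = series.times
        lo, hi = epochset.window
        sel = (t >= onset + lo - _EPS) & (t <= onset + hi + _EPS)
        if sel.sum() < 2:
            continue
        var = series.values[:, sel].var(axis=1, ddof=1)
        out[i] = np.log(np.maximum(var, 1e-300)).mean()
    return out


def reject_outlier_epochs(epochset: EpochSet, series, alpha: float = 0.05) -> EpochSet:
    """Flag artefact epochs by generalized ESD on log epoch variance.

    ``series`` is a VoxelSeries (single block) or ``{block_id: VoxelSeries}``.
    With fewer than 3 epochs all are accepted and a warning is logged.
    ``alpha = 0`` rejects nothing.
    """
    if isinstance(series, VoxelSeries):
        series = {str(series.block_id): series}
    if len(epochset) < 3:
        logger.warning("fewer than 3 epochs (%d): outlier test skipped", len(epochset))
        return epochset
    summary = _epoch_log_variance(epochset, series)
    candidates = np.flatnonzero(epochset.accepted & np.isfinite(summary))
    flagged = generalized_esd(summary[candidates], alpha=alpha)
    accepted = epochset.accepted.copy()
    accepted[candidates[flagged]] = False
    frac = accepted.sum() / max(1, len(epochset))
    logger.info("%s epochs: %d/%d accepted (%.1f%%)", epochset.kind,
                accepted.sum(), len(epochset), 100 * frac)
    return replace(epochset, accepted=accepted)


def save_epochs(epochsets: list, path):
    with h5py.File(path, "w") as f:
        for i, es in enumerate(epochsets):
            g = f.create_group(f"epochset_{i}")
            g.attrs["kind"] = es.kind
            g.attrs["window"] = list(es.window)
            g.create_dataset("onsets", data=es.onsets)
            g.create_dataset("accepted", data=es.accepted)
            g.create_dataset("block_id", data=np.array(es.block_id, dtype="S"))
            g.create_dataset("bout_end", data=es.bout_end)


def load_epochs(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            out.append(EpochSet(
                kind=g.attrs["kind"], onsets=g["onsets"][()],
                window=tuple(g.attrs["window"]), accepted=g["accepted"][()],
                block_id=np.array([s.decode() for s in g["block_id"][()]]),
                bout_end=g["bout_end"][()],
            ))
    return out
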