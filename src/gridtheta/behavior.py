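"""Behavioral measures: spatial-memory performance, movement-duration
statistics and boundary preference."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .navio import TrajectoryLog

__all__ = ["PerformanceScore", "performance", "movement_stats", "boundary_preference"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerformanceScore:
    mean_error_vm: float
    score: float          # 1/vm; larger is better
    n_trials: int


def performance(responses: pd.DataFrame, mode: str = "average_then_invert") -> PerformanceScore:
    """Spatial-memory performance: inverse distance between remembered and
    actual object locations over retrieval trials.

    Default is the reciprocal of the mean error distance
    (``average_then_invert``); ``invert_then_average`` averages per-trial
    reciprocals instead.  A zero mean distance yields an infinite score.
    """
    ret = responses[responses["phase"] == "retrieval"] if "phase" in responses else responses
    if len(ret) < 1:
        raise InvalidArgumentError("need >= 1 retrieval response")
    d = np.hypot(ret["resp_x"] - ret["true_x"], ret["resp_y"] - ret["true_y"]).to_numpy()
    if mode == "average_then_invert":
        mean_d = float(d.mean())
        if mean_d == 0:
            logger.warning("all responses perfect: score is infinite")
            return PerformanceScore(0.0, float("inf"), len(ret))
        return PerformanceScore(mean_d, 1.0 / mean_d, len(ret))
    if mode == "invert_then_average":
        with np.errstate(divide="ignore"):
            inv = np.where(d == 0, np.inf, 1.0 / d)
        return PerformanceScore(float(d.mean()), float(inv.mean()), len(ret))
    raise InvalidArgumentError(f"unknown mode {mode!r}")


def movement_stats(traj: TrajectoryLog):
    """Mean duration (s) of continuous translation bouts (all bouts)."""
    durations = []
    for bid in traj.blocks():
        tb = traj.block(bid)
        dt = 1.0 / tb.sample_rate
        padded = np.concatenate([[False], tb.moving, [False]]).astype(int)
        d = np.diff(padded)
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            durations.append((e - s) * dt)
    if not durations:
        return float("nan")
    return float(np.mean(durations))


def boundary_preference(traj: TrajectoryLog, margin_vm: float = 25.0,
                        side_length: float = 100.0) -> float:
    """Percentage of moving samples within ``margin_vm`` of the nearest wall."""
    if not (0.0 < margin_vm < side_length / 2.0):
        raise InvalidArgumentError("margin must lie in (0, side/2)")
    x, y = traj.x[traj.moving], traj.y[traj.moving]
    if x.size == 0:
        return float("nan")
    wall = np.minimum(np.minimum(x, side_length - x), np.minimum(y, side_length - y))
    return float(100.0 * np.mean(wall <= margin_vm))
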