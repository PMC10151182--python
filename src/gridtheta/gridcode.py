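"""Cross-validated quadrature-filter estimation of n-fold directional
modulation of band power.

The quadrature filter regresses continuous Z-scored band power on
``[1, cos(n theta), sin(n theta)]`` over movement samples of one data fold;
the grid orientation is ``phi = atan2(b_sin, b_cos) / n`` folded into
``[0, 360/n)``.  The modulation strength beta is then the slope of power on
``cos(n (theta - phi))`` over the held-out fold.  Folds are alternate
movement-onset epochs; the roles are reversed, betas averaged across the
two folds and then across task blocks, giving one beta per voxel per
participant.  The fold-reversal design makes beta unbiased (zero mean)
under the null of no directional modulation.  Control analyses repeat the
pipeline for 4-, 5-, 7- and 8-fold symmetry and for delta, alpha, beta and
gamma bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, OrientationUndefinedError
from . import navio, circstat
from .epochs import EpochSet
from .navio import TrajectoryLog
from .spectral import BandPowerSeries

__all__ = [
    "GridFit",
    "BlockSamples",
    "movement_samples",
    "split_alternate",
    "estimate_orientation",
    "regress_modulation",
    "crossval_grid",
    "aligned_contrast",
    "control_analyses",
]

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class GridFit:
    voxel: int
    block_id: str
    fold: str                 # "A" | "B": the fold beta was evaluated on
    n_fold: int
    orientation_deg: float    # estimated on the OTHER fold, in [0, 360/n)
    beta_cos: float
    beta_sin: float
    beta: float               # Z-power units per unit cosine
    n_samples: int


@dataclass
class BlockSamples:
    """Paired (power, direction) movement samples of one block."""

    block_id: str
    power: np.ndarray        # n_samples x n_voxels, Z-units
    direction_deg: np.ndarray
    epoch_index: np.ndarray  # which accepted epoch each sample came from
    envelope_sd: np.ndarray  # per-voxel SD used for Z-scoring (de-standardize)


def movement_samples(epochset: EpochSet, traj: TrajectoryLog,
                     power: BandPowerSeries,
                     exclude_mask: np.ndarray | None = None) -> BlockSamples:
    """Continuous movement samples following each accepted movement onset.

    For each accepted epoch, takes every signal sample from the onset to the
    end of that continuous translation bout, pairing Z-power with the
    nearest-neighbour movement direction.  Samples with invalid direction or
    flagged by the overlap-exclusion mask are dropped listwise.
    """
    series = navio.VoxelSeries(power.sample_rate, power.start_time, power.values,
                               block_id=power.block_id)
    aligned = navio.align_direction_to_signal(traj, series)
    t = series.times
    keep_pow, keep_dir, keep_ep = [], [], []
    for ei, (onset, acc, end) in enumerate(zip(epochset.onsets, epochset.accepted,
                                               epochset.bout_end)):
        if not acc:
            continue
        # [onset, bout end) is the translation period by construction; the
        # nearest behavioral index is clipped into the bout so boundary
        # samples take the bout's own heading
        sel = (t >= onset - _EPS) & (t < end - _EPS)
        if exclude_mask is not None:
            sel &= ~exclude_mask
        if not np.any(sel):
            logger.info("epoch %d at %.2f s: no translation samples, skipped", ei, onset)
            continue
        i_lo = int(np.searchsorted(traj.t, onset - _EPS))
        i_hi = int(np.searchsorted(traj.t, end - _EPS)) - 1
        idx = np.clip(aligned.index[sel], i_lo, max(i_lo, i_hi))
        keep_pow.append(power.values[:, sel].T)
        keep_dir.append(traj.heading[idx])
        keep_ep.append(np.full(int(sel.sum()), ei))
    if not keep_pow:
        return BlockSamples(str(epochset.block_id[0]) if len(epochset) else "?",
                            np.empty((0, power.values.shape[0])), np.empty(0),
                            np.empty(0, dtype=int), power.sd)
    return BlockSamples(str(epochset.block_id[0]),
                        np.vstack(keep_pow), np.concatenate(keep_dir),
                        np.concatenate(keep_ep), power.sd)


def split_alternate(epoch_indices) -> tuple:
    """Alternate split by temporal order: odd-numbered epochs (1st, 3rd, ...)
    to fold A, even-numbered to fold B."""
    idx = np.unique(np.asarray(epoch_indices))
    if idx.size < 2:
        raise InvalidArgumentError("need >= 2 accepted epochs to split")
    return idx[0::2], idx[1::2]


def estimate_orientation(power, direction_deg, n: int = 6):
    """Quadrature filter: least squares of power on [1, cos(n t), sin(n t)].

    Returns ``(phi_deg in [0, 360/n), (beta_cos, beta_sin))``.
    """
    p = np.asarray(power, dtype=float)
    th = np.deg2rad(np.asarray(direction_deg, dtype=float)) * n
    if p.size < 3:
        raise InvalidArgumentError("need >= 3 samples")
    X = np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])
    coef, _, rank, _ = np.linalg.lstsq(X, p, rcond=None)
    if rank < 3:
        raise OrientationUndefinedError("rank-deficient directional design")
    b_cos, b_sin = float(coef[1]), float(coef[2])
    phi = np.rad2deg(np.arctan2(b_sin, b_cos)) / n
    return float(circstat.fold(phi, n)), (b_cos, b_sin)


def regress_modulation(power, direction_deg, phi_deg: float, n: int = 6) -> float:
    """Slope of power on cos(n (theta - phi)), with intercept."""
    p = np.asarray(power, dtype=float)
    if p.size < 3:
        raise InvalidArgumentError("need >= 3 samples")
    x = np.cos(np.deg2rad((np.asarray(direction_deg, dtype=float) - phi_deg)) * n)
    X = np.column_stack([np.ones_like(x), x])
    coef, _, rank, _ = np.linalg.lstsq(X, p, rcond=None)
    if rank < 2:
        raise OrientationUndefinedError("degenerate cosine regressor")
    return float(coef[1])


def crossval_grid(blocks: list, n: int = 6):
    """Fold-reversed cross-validated beta per voxel, averaged over blocks.

    ``blocks`` is a list of :class:`BlockSamples`.  For each block, fold A's
    orientation scores fold B's samples and vice versa; betas are averaged
    across the two folds, then across blocks.  Returns
    ``(beta per voxel, list of GridFit)``; blocks with < 2 usable epochs are
    excluded (participant-level NaN if none remain).
    """
    n_vox = blocks[0].power.shape[1] if blocks else 0
    per_block = []
    fits = []
    for bs in blocks:
        try:
            fold_a, fold_b = split_alternate(bs.epoch_index)
        except InvalidArgumentError:
            logger.info("block %s: < 2 epochs, excluded", bs.block_id)
            continue
        in_a = np.isin(bs.epoch_index, fold_a)
        in_b = ~in_a
        betas = np.full(n_vox, np.nan)
        for v in range(n_vox):
            try:
                res = []
                for est, ev, name in ((in_a, in_b, "B"), (in_b, in_a, "A")):
                    phi, (bc, bsin) = estimate_orientation(
                        bs.power[est, v], bs.direction_deg[est], n)
                    beta = regress_modulation(
                        bs.power[ev, v], bs.direction_deg[ev], phi, n)
                    fits.append(GridFit(v, bs.block_id, name, n, phi, bc, bsin,
                                        beta, int(ev.sum())))
                    res.append(beta)
                betas[v] = np.mean(res)
            except (InvalidArgumentError, OrientationUndefinedError):
                continue
        per_block.append(betas)
    if not per_block:
        logger.warning("all blocks excluded: participant beta undefined")
        return np.full(n_vox, np.nan), fits
    return np.nanmean(np.array(per_block), axis=0), fits


def aligned_contrast(power, direction_deg, phi_deg: float, n: int = 6,
                     width_deg: float = 15.0):
    """Aligned-minus-misaligned power and the aligned sample fraction.

    A sample is aligned iff its absolute deviation from the nearest grid
    axis (phi plus multiples of 360/n) is <= ``width_deg``.  For uniform
    directions with n = 6 and width 15 degrees, half the samples are aligned.
    """
    if not (0 < width_deg < 180.0 / n):
        raise InvalidArgumentError("width must lie in (0, half period)")
    p = np.asarray(power, dtype=float)
    dev = np.abs(circstat.circ_dev_nfold(direction_deg, phi_deg, n))
    alig = dev <= width_deg + _EPS
    if not np.any(alig) or np.all(alig):
        raise InvalidArgumentError("no aligned or no misaligned samples")
    diff = float(p[alig].mean() - p[~alig].mean())
    return diff, float(alig.mean())


def crossval_aligned_contrast(blocks: list, voxel: int = 0, n: int = 6,
                              width_deg: float = 15.0):
    """Cross-validated aligned contrast: each fold scored with the other
    fold's orientation, averaged over folds then blocks.

    Returns ``(power difference, aligned fraction)`` (NaN, NaN if undefined).
    """
    diffs, fracs = [], []
    for bs in blocks:
        try:
            fold_a, fold_b = split_alternate(bs.epoch_index)
        except InvalidArgumentError:
            continue
        in_a = np.isin(bs.epoch_index, fold_a)
        for est, ev in ((in_a, ~in_a), (~in_a, in_a)):
            try:
                phi, _ = estimate_orientation(bs.power[est, voxel],
                                              bs.direction_deg[est], n)
                d, f = aligned_contrast(bs.power[ev, voxel],
                                        bs.direction_deg[ev], phi, n, width_deg)
            except (InvalidArgumentError, OrientationUndefinedError):
                continue
            diffs.append(d)
            fracs.append(f)
    if not diffs:
        return float("nan"), float("nan")
    return float(np.mean(diffs)), float(np.mean(fracs))


def control_analyses(samples_by_band: dict, voxel: int = 0,
                     symmetries=(4, 5, 6, 7, 8)) -> pd.DataFrame:
    """Beta table over rotational symmetries x frequency bands for one voxel.

    ``samples_by_band`` maps band name -> list of BlockSamples (band power
    recomputed per band upstream).  Returns a tidy DataFrame with columns
    ``symmetry, band, beta``.
    """
    rows = []
    for band_name, blocks in samples_by_band.items():
        for n in symmetries:
            beta, _ = crossval_grid(blocks, n=n)
            rows.append((n, band_name, float(beta[voxel])))
    return pd.DataFrame(rows, columns=["symmetry", "band", "beta"])
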