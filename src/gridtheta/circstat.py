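"""Circular statistics in n-fold symmetric space.

Grid orientations are phases of an n-fold directional modulation and live on
a circle of period ``360/n`` degrees ("folded space").  This module provides
folding, wrap-aware means, an orientation-consistency statistic (mean
absolute circular deviation) and its chance level for uniform orientations,
which is ``180/(2n)`` degrees — 15 degrees for the hexadirectional case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, UndefinedMeanError
from .cohortstats import one_sample_t, TestResult

__all__ = [
    "FoldedOrientation",
    "fold",
    "circ_mean_nfold",
    "circ_dev_nfold",
    "consistency",
    "chance_consistency",
    "consistency_tests",
]


@dataclass(frozen=True)
class FoldedOrientation:
    """An orientation in ``[0, 360/n_fold)`` degrees."""

    value: float
    n_fold: int

    def __post_init__(self):
        if self.n_fold < 1:
            raise InvalidArgumentError("n_fold must be >= 1")
        if not (0.0 <= self.value < 360.0 / self.n_fold):
            raise InvalidArgumentError(
                f"orientation {self.value} outside [0, {360.0 / self.n_fold})"
            )

    @property
    def period(self) -> float:
        return 360.0 / self.n_fold


def fold(angle_deg, n: int):
    """Reduce angle(s) modulo the n-fold period ``360/n`` degrees."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    return np.asarray(angle_deg, dtype=float) % (360.0 / n)


def circ_mean_nfold(orientations_deg, n: int) -> FoldedOrientation:
    """Wrap-aware mean of orientations in n-fold space.

    Angles are multiplied by ``n`` to map the folded circle onto the full
    circle, vector averaged, and the resultant angle divided by ``n``.
    """
    ang = np.atleast_1d(np.asarray(orientations_deg, dtype=float))
    if ang.size == 0:
        raise InvalidArgumentError("need at least one orientation")
    z = np.exp(1j * np.deg2rad(ang) * n)
    r = z.mean()
    if abs(r) < 1e-12:
        raise UndefinedMeanError("zero resultant: circular mean undefined")
    mean = np.rad2deg(np.angle(r)) / n
    return FoldedOrientation(float(fold(mean, n)), n)


def circ_dev_nfold(a_deg, b_deg, n: int):
    """Signed smallest deviation a - b in n-fold space, in (-180/n, 180/n]."""
    period = 360.0 / n
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % period
    half = period / 2.0
    return np.where(d > half, d - period, d)


def consistency(orientations_deg, n: int, mode: str = "deviation") -> float:
    """Orientation consistency as mean absolute circular deviation (degrees).

    ``mode="deviation"`` (default): mean absolute deviation of each
    orientation from the set's n-fold circular mean; always in
    ``[0, 180/n]``.  ``mode="pairwise"`` is defined for exactly two
    orientations and returns their folded absolute difference (twice the
    deviation-from-mean value), used when comparing two data partitions.
    """
    ang = np.atleast_1d(np.asarray(orientations_deg, dtype=float))
    if mode == "pairwise":
        if ang.size != 2:
            raise InvalidArgumentError("pairwise mode needs exactly 2 orientations")
        return float(abs(circ_dev_nfold(ang[0], ang[1], n)))
    if mode != "deviation":
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if ang.size < 2:
        raise InvalidArgumentError("need >= 2 orientations")
    mean = circ_mean_nfold(ang, n).value
    return float(np.mean(np.abs(circ_dev_nfold(ang, mean, n))))


def chance_consistency(
    n: int,
    mode: str = "analytic",
    m: int = 2,
    reps: int = 100_000,
    seed: int | None = None,
):
    """Chance level of the consistency statistic for uniform orientations.

    Analytic mode returns the asymptote ``180/(2n)`` degrees: the expected
    absolute circular deviation of a uniform orientation from any fixed
    point of the folded space.  Monte Carlo mode simulates ``m`` uniform
    orientations per repetition and returns ``(mean, standard error)`` of
    the finite-sample consistency, which deviates from the asymptote for
    small ``m``.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if mode == "analytic":
        return 180.0 / (2.0 * n)
    if mode != "monte_carlo":
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if reps < 1 or m < 2:
        raise InvalidArgumentError("reps >= 1 and m >= 2 required")
    rng = np.random.default_rng(seed)
    period = 360.0 / n
    ang = rng.uniform(0.0, period, size=(reps, m))
    if m == 2:
        d = np.abs(ang[:, 0] - ang[:, 1]) % period
        half = period / 2.0
        vals = np.where(d > half, period - d, d)
    else:
        vals = np.empty(reps)
        for i in range(reps):
            vals[i] = consistency(ang[i], n)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(reps))


def consistency_tests(
    participant_consistencies, n: int = 6, chance: float | None = None
) -> TestResult:
    """One-sample t of per-participant consistencies against chance.

    Negative t means orientations are more consistent (smaller deviations)
    than expected for uniform orientations.
    """
    vals = np.asarray(participant_consistencies, dtype=float)
    if vals.size < 2:
        raise InvalidArgumentError("need >= 2 participants")
    if chance is None:
        chance = chance_consistency(n, "analytic")
    return one_sample_t(vals, chance)
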