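"""Group-level inference: t-tests, Hedges' g with noncentral-t CI,
Pearson correlations, and a sign-flip max-statistic permutation map.

Two-sample comparisons use the pooled-variance (Student) t so that a
23-versus-17 comparison reports the conventional ``df = n1 + n2 - 2 = 38``.
Effect sizes are Hedges' g: the pooled standardized mean difference with the
small-sample correction ``J = 1 - 3/(4 df - 1)``; its confidence interval is
obtained by inverting the noncentral-t distribution of the observed t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import InvalidArgumentError

__all__ = [
    "TestResult",
    "GroupComparison",
    "two_sample_t",
    "hedges_g",
    "one_sample_t",
    "pearson",
    "instability_performance_correlation",
    "max_stat_permutation",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    df: float
    p: float
    g: float = float("nan")
    g_ci: tuple = (float("nan"), float("nan"))
    mean_a: float = float("nan")
    sd_a: float = float("nan")
    mean_b: float = float("nan")
    sd_b: float = float("nan")
    n_a: int = 0
    n_b: int = 0


def _check_group(x, name):
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidArgumentError(f"group {name} needs >= 2 values")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError(f"group {name} contains non-finite values")
    return x


def two_sample_t(group_a, group_b, effect_size: bool = True) -> GroupComparison:
    """Pooled-variance Student t (two-sided), with Hedges' g by default."""
    a = _check_group(group_a, "A")
    b = _check_group(group_b, "B")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise InvalidArgumentError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    g, ci = (float("nan"), (float("nan"), float("nan")))
    if effect_size:
        g, ci = hedges_g(a, b)
    return GroupComparison(
        statistic=float(t), df=float(df), p=float(p), g=g, g_ci=ci,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        n_a=n1, n_b=n2,
    )


def hedges_g(group_a, group_b, ci_level: float = 0.95):
    """Hedges' g and its CI via noncentral-t inversion.

    g = J * (mean_a - mean_b) / s_pooled with J = 1 - 3/(4 df - 1).  The CI
    inverts Pr[T_df(delta) <= t_obs] for the noncentrality delta, then maps
    delta back to the effect-size scale (and applies J).  Falls back to a
    normal approximation if the inversion fails to bracket.
    """
    a = _check_group(group_a, "A")
    b = _check_group(group_b, "B")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise InvalidArgumentError("zero pooled variance")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)  # t = d / scale
    t_obs = d / scale
    alpha = 1.0 - ci_level

    def _delta_for(prob):
        # delta such that nct.cdf(t_obs; df, delta) == prob
        f = lambda delta: stats.nct.cdf(t_obs, df, delta) - prob
        lo, hi = t_obs - 20.0 - 10.0 * abs(t_obs), t_obs + 20.0 + 10.0 * abs(t_obs)
        try:
            return optimize.brentq(f, lo, hi, xtol=1e-8)
        except ValueError:
            # normal-approximation fallback
            se = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * df))
            zq = stats.norm.ppf(prob)
            return (g + zq * se) / (j * scale)

    d_lo = _delta_for(1.0 - alpha / 2.0) * scale
    d_hi = _delta_for(alpha / 2.0) * scale
    return float(g), (float(j * d_lo), float(j * d_hi))


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Standard one-sample t against ``mu0``, two-sided."""
    x = _check_group(values, "values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InvalidArgumentError("zero variance")
    t = (x.mean() - mu0) / (sd / np.sqrt(x.size))
    df = x.size - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), float(x.mean()), float(sd), x.size)


def pearson(x, y):
    """Pearson correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidArgumentError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidArgumentError("constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def instability_performance_correlation(across_block_consistency, performance):
    """Pearson r of across-block orientation (in)consistency vs performance.

    Negative r: participants whose grid orientation is stable across blocks
    (small consistency value) perform better.
    """
    return pearson(across_block_consistency, performance)


def max_stat_permutation(values, n_perm: int = 1000, seed: int | None = None):
    """Per-voxel one-sample t with sign-flip max-|t| familywise correction.

    ``values`` is participants x voxels.  Returns (t per voxel, FWE-corrected
    p per voxel).  Stands in for cluster-level random-field inference on the
    small synthetic voxel grid.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidArgumentError("need participants x voxels with >= 2 rows")
    n = x.shape[0]

    def _tvec(m):
        sd = m.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.nan, sd)
        return m.mean(axis=0) / (sd / np.sqrt(n))

    t_obs = _tvec(x)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=(n, 1))
        max_null[i] = np.nanmax(np.abs(_tvec(x * flips)))
    p_fwe = (1.0 + np.sum(max_null[None, :] >= np.abs(t_obs)[:, None], axis=1)) / (
        n_perm + 1.0
    )
    return t_obs, p_fwe
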