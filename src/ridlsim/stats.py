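"""Trend fits, autocorrelation and permutation tests for trajectories.

Proportion series are variance-stabilized with the arc-sine square-root
transform and fitted with an ordinary least-squares quadratic in
generation.  Residual series are screened for lag-1 autocorrelation
(the signature of a release policy that reacts to the previous
generation's resistance peak).  Treatment contrasts on replicate-level
summaries use permutation tests, which are exact under exchangeability
and need no distributional model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "arcsine_sqrt",
    "TrendFit",
    "fit_quadratic_trend",
    "lag1_autocorrelation",
    "PermutationResult",
    "permutation_treatment_test",
]


def arcsine_sqrt(p) -> np.ndarray:
    """Arc-sine square-root transform of proportions in [0, 1]."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must be in [0, 1]")
    return np.arcsin(np.sqrt(p))


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of transformed proportions on (1, generation, generation^2)."""

    intercept: float
    linear: float
    quadratic: float
    generations: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    linear_only: bool = False

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.intercept, self.linear, self.quadratic)


def fit_quadratic_trend(
    proportions: Sequence[float],
    generations: Sequence[float] | None = None,
    transform: bool = True,
) -> TrendFit:
    """Quadratic trend of arcsin(sqrt(p)) against generation.

    Missing (NaN) values are dropped.  With fewer than 3 defined points
    a linear-only fit is returned, flagged via ``linear_only`` (the
    quadratic coefficient is 0).
    """
    p = np.asarray(proportions, dtype=float)
    g = (
        np.arange(len(p), dtype=float)
        if generations is None
        else np.asarray(generations, dtype=float)
    )
    if len(p) != len(g):
        raise ValueError("proportions and generations must have equal length")
    keep = ~np.isnan(p)
    p, g = p[keep], g[keep]
    if len(p) < 2:
        raise ValueError("need at least 2 defined values to fit a trend")
    y = arcsine_sqrt(p) if transform else p
    linear_only = len(p) < 3
    if linear_only:
        design = np.column_stack([np.ones_like(g), g])
    else:
        design = np.column_stack([np.ones_like(g), g, g**2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    residuals = y - fitted
    if linear_only:
        coef = np.append(coef, 0.0)
    return TrendFit(
        intercept=float(coef[0]),
        linear=float(coef[1]),
        quadratic=float(coef[2]),
        generations=g,
        fitted=fitted,
        residuals=residuals,
        linear_only=linear_only,
    )


def lag1_autocorrelation(residuals: Sequence[float]) -> float:
    """Lag-1 serial correlation of a short residual series, in [-1, 1].

    Uses the circular serial correlation coefficient about the series
    mean, r = sum(c_t * c_{t+1 mod n}) / sum(c_t^2), the classical
    estimator whose expectation for a white-noise series is exactly
    -1/(n-1) — the small-sample negative bias any analysis of 4-point
    detrended series must account for.  Returns NaN (degenerate) for a
    constant series, which has no variance to correlate.
    """
    x = np.asarray(residuals, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 residuals for lag-1 autocorrelation")
    c = x - x.mean()
    den = float((c**2).sum())
    if den == 0.0:
        return math.nan
    return float((c * np.roll(c, -1)).sum() / den)


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation test on replicate-level summaries."""

    p_value: float
    observed: float
    n_perm: int
    exhaustive: bool
    alternative: str


def _between_group_stat(values: np.ndarray, sizes: Sequence[int]) -> float:
    """Spread of group means (k groups); signed mean difference for k=2."""
    means = []
    start = 0
    for n in sizes:
        means.append(values[start : start + n].mean())
        start += n
    if len(sizes) == 2:
        return means[0] - means[1]
    grand = values.mean()
    return float(sum(n * (m - grand) ** 2 for n, m in zip(sizes, means)))


def permutation_treatment_test(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    n_perm: int = 9999,
    rng: np.random.Generator | None = None,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> PermutationResult:
    """Permutation test of a treatment effect on replicate summaries.

    For two groups the statistic is the difference in group means
    (first minus second); directional alternatives refer to that sign.
    For more than two groups the statistic is the between-group sum of
    squares and only the two-sided alternative is available.  When all
    distinct relabelings of two groups number at most ``n_perm`` the
    test enumerates them exhaustively (exact p = extreme/total);
    otherwise ``n_perm`` random relabelings are drawn and
    p = (1 + extreme) / (1 + n_perm).  Deterministic given ``rng``.
    """
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 treatment groups")
    sizes = [len(a) for a in arrays]
    if min(sizes) < 2:
        raise ValueError("need at least 2 replicates per group")
    if len(arrays) > 2 and alternative != "two-sided":
        raise ValueError("directional alternatives require exactly 2 groups")
    pooled = np.concatenate(arrays)
    observed = _between_group_stat(pooled, sizes)

    def extremity(stat: float) -> bool:
        if alternative == "two-sided":
            return abs(stat) >= abs(observed) - 1e-12
        if alternative == "greater":
            return stat >= observed - 1e-12
        return stat <= observed + 1e-12

    n_total = len(pooled)
    if len(arrays) == 2 and math.comb(n_total, sizes[0]) <= n_perm:
        count = 0
        total = 0
        idx = np.arange(n_total)
        for combo in itertools.combinations(idx, sizes[0]):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(combo)] = True
            stat = pooled[mask].mean() - pooled[~mask].mean()
            count += extremity(stat)
            total += 1
        return PermutationResult(
            p_value=count / total,
            observed=observed,
            n_perm=total,
            exhaustive=True,
            alternative=alternative,
        )

    rng = rng or np.random.default_rng()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += extremity(_between_group_stat(perm, sizes))
    return PermutationResult(
        p_value=(1 + count) / (1 + n_perm),
        observed=observed,
        n_perm=n_perm,
        exhaustive=False,
        alternative=alternative,
    )
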