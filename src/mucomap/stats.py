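"""Nonparametric group statistics and simple linear regression.

Implements the rank-based toolkit used for ordinal mucus-score and ratio
comparisons: Mann-Whitney U (exact by enumeration for small samples, normal
approximation with tie and continuity correction otherwise), Bonferroni-Dunn
multiplicity adjustment, Kruskal-Wallis with tie correction, Dunn's pairwise
post-hoc z tests, Pearson correlation and ordinary least squares.

Conventions (fixed so results are reproducible bit-for-bit):

* U is the number of pairs ``(a_i, b_j)`` with ``a_i < b_j`` plus half the
  tied pairs; the reported statistic is ``min(U, n_a*n_b - U)``.
* All p values are two-sided.
* The normal approximation uses a continuity correction of 0.5.
* All-tied Kruskal-Wallis input returns H = 0 with p = 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "RegressionResult",
    "mann_whitney_u",
    "bonferroni_dunn_adjust",
    "kruskal_wallis",
    "dunn_posthoc",
    "pearson_r",
    "simple_linreg",
]

_EXACT_MAX_N = 8  # per-group limit below which "auto" picks full enumeration


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test.

    ``p_adjusted`` is ``None`` unless a multiplicity adjustment was applied.
    ``groups`` identifies the compared groups for post-hoc results.
    """

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    p_adjusted: float | None = None
    groups: tuple[int, int] | None = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int


def _as_1d(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _pair_u(a: np.ndarray, b: np.ndarray) -> float:
    """Number of (a_i, b_j) pairs with a_i < b_j, plus half the ties."""
    diff = b[None, :] - a[:, None]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode`` is one of ``"exact"`` (full enumeration of group-label
    assignments), ``"normal-approx"``, or ``"auto"`` (exact when both group
    sizes are <= 8).
    """
    xa = _as_1d(a, "a")
    xb = _as_1d(b, "b")
    na, nb = xa.size, xb.size
    if mode not in ("exact", "normal-approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if (na <= _EXACT_MAX_N and nb <= _EXACT_MAX_N) else "normal-approx"

    nm = na * nb
    u = _pair_u(xa, xb)
    u_min = min(u, nm - u)

    if mode == "exact":
        pooled = np.concatenate([xa, xb])
        total = 0
        at_least_as_extreme = 0
        idx = np.arange(pooled.size)
        for comb in itertools.combinations(idx, na):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(comb)] = True
            u_perm = _pair_u(pooled[mask], pooled[~mask])
            if min(u_perm, nm - u_perm) <= u_min + 1e-12:
                at_least_as_extreme += 1
            total += 1
        p = at_least_as_extreme / total
        return TestResult(u_min, p, (na, nb), "mann-whitney-exact")

    pooled = np.concatenate([xa, xb])
    n_total = na + nb
    mu = nm / 2.0
    tie = _tie_term(pooled)
    var = nm / 12.0 * ((n_total + 1) - tie / (n_total * (n_total - 1)))
    if var <= 0:  # all observations tied
        return TestResult(u_min, 1.0, (na, nb), "mann-whitney-normal")
    z = (u_min - mu + 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * norm.cdf(z))
    return TestResult(u_min, p, (na, nb), "mann-whitney-normal")


def bonferroni_dunn_adjust(
    p_values: Sequence[float], m: int | None = None
) -> list[float]:
    """Bonferroni-Dunn adjustment: p_adj = min(1, p * m), order preserved."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError(f"m={m} smaller than number of p values ({len(ps)})")
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p value {p} outside [0, 1]")
    return [min(1.0, p * m) for p in ps]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with mid-ranks and tie correction."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    arrs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    sizes = [a.size for a in arrs]
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("kruskal_wallis needs total n >= 3")
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for sz in sizes:
        r_sum = float(np.sum(ranks[start : start + sz]))
        h += r_sum**2 / sz
        start += sz
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0:  # every observation identical
        return TestResult(0.0, 1.0, tuple(sizes), "kruskal-wallis")
    h /= correction
    h = max(h, 0.0)
    p = float(chi2.sf(h, df=len(groups) - 1))
    return TestResult(h, p, tuple(sizes), "kruskal-wallis")


def dunn_posthoc(
    groups: Sequence[Sequence[float]], adjust: bool = True
) -> list[TestResult]:
    """Dunn's pairwise post-hoc z tests on mean ranks.

    Returns one :class:`TestResult` per unordered group pair, with
    Bonferroni-Dunn adjusted p values when ``adjust`` is true.
    """
    if len(groups) < 2:
        raise ValueError("dunn_posthoc needs at least 2 groups")
    arrs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    sizes = [a.size for a in arrs]
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(float(np.mean(ranks[start : start + sz])))
        start += sz
    var_base = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (
        12.0 * (n_total - 1)
    )
    pairs = list(itertools.combinations(range(len(groups)), 2))
    raw: list[tuple[float, float, tuple[int, int]]] = []
    for i, j in pairs:
        se2 = var_base * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se2)
        p = min(1.0, 2.0 * norm.sf(abs(z)))
        raw.append((z, p, (i, j)))
    adjusted = (
        bonferroni_dunn_adjust([p for _, p, _ in raw], len(pairs))
        if adjust
        else [None] * len(raw)
    )
    return [
        TestResult(
            z,
            p,
            (sizes[i], sizes[j]),
            "dunn-posthoc",
            p_adjusted=p_adj,
            groups=(i, j),
        )
        for (z, p, (i, j)), p_adj in zip(raw, adjusted)
    ]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("pearson_r needs n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("pearson_r undefined for constant input")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    return float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def simple_linreg(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided slope t test."""
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("simple_linreg needs n >= 3")
    if np.ptp(xa) == 0:
        raise ValueError("simple_linreg undefined for constant x")
    xc = xa - xa.mean()
    sxx = float(np.dot(xc, xc))
    slope = float(np.dot(xc, ya)) / sxx
    intercept = float(ya.mean() - slope * xa.mean())
    fitted = slope * xa + intercept
    ss_res = float(np.sum((ya - fitted) ** 2))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    if ss_tot == 0:  # constant y: flat fit by convention
        return RegressionResult(slope, intercept, 0.0, 0.0, 1.0, n)
    r_squared = 1.0 - ss_res / ss_tot
    r = math.copysign(math.sqrt(max(r_squared, 0.0)), slope)
    if ss_res <= 0:
        p = 0.0
    else:
        se = math.sqrt(ss_res / (n - 2) / sxx)
        t_stat = slope / se
        p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
    return RegressionResult(slope, intercept, r, r_squared, p, n)
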