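"""Resampling and nonparametric test utilities.

Shared by the encoding and decoding analyses: percentile bootstrap
confidence intervals across cross-validation folds, the Wilcoxon
signed-rank test (exact by complete enumeration of sign assignments for
small n), the Wilcoxon rank-sum test, and the Bonferroni-adjusted CI level
used for simultaneous per-component intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ConfidenceInterval",
    "TestResult",
    "bootstrap_ci",
    "bootstrap_ci_rows",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "bonferroni_level",
]

# Exact null enumeration is used up to these sample sizes; beyond them the
# normal approximation (with continuity and tie corrections) takes over.
EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_N = 20


@dataclass(frozen=True)
class ConfidenceInterval:
    level: float
    lo: float
    hi: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level must be in (0,1), got {self.level}")
        if self.lo > self.hi:
            raise ValueError("lo > hi")

    def excludes(self, value: float) -> bool:
        return value < self.lo or value > self.hi


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: int
    exact: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def bootstrap_ci(
    values, level: float = 0.95, n_boot: int = 10_000, seed: int = 0
) -> ConfidenceInterval:
    """Percentile bootstrap CI for the mean of ``values``.

    Resamples the values with replacement ``n_boot`` times and takes the
    (1-level)/2 and (1+level)/2 percentiles of the resampled means.
    Deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0,1), got {level}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return ConfidenceInterval(level, float(lo), float(hi), n_boot, seed)


def bootstrap_ci_rows(
    values: np.ndarray, level: float, n_boot: int, seed: int
) -> np.ndarray:
    """Percentile bootstrap CIs of the column means of a (rows x q) array.

    One resampling of the rows is shared across all columns, which is what
    resampling cross-validation folds means when each fold carries a whole
    time course.  Returns an array (q, 2) of (lo, hi).  Memory is kept
    bounded by chunking over columns.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows")
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    alpha = (1.0 - level) / 2.0
    out = np.empty((values.shape[1], 2))
    chunk = max(1, int(2e6 // max(n_boot, 1)))
    for start in range(0, values.shape[1], chunk):
        block = values[:, start : start + chunk]  # (n, c)
        means = block[idx].mean(axis=1)  # (n_boot, c)
        out[start : start + chunk, 0] = np.quantile(means, alpha, axis=0)
        out[start : start + chunk, 1] = np.quantile(means, 1.0 - alpha, axis=0)
    return out


def _signed_rank_exact_sf(ranks2: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W+ by dynamic programming over sign patterns.

    ``ranks2`` are the (tie-averaged) ranks doubled so they are integers.
    Equivalent to enumerating all 2^n sign assignments: each rank enters the
    positive-rank sum independently with probability 1/2.  Returns the
    probability mass function over 0..sum(ranks2).
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(values, mu0: float = 0.0) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of location against ``mu0``.

    Zero differences are dropped (Wilcoxon's rule).  For n <= 25 the exact
    two-sided p-value is computed from the complete null distribution of
    the positive-rank sum (tie-aware); for larger n a normal approximation
    with continuity and tie corrections is used.  If every difference is
    zero the result is degenerate with p = 1.
    """
    d = np.asarray(values, dtype=float).ravel() - mu0
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(
            "wilcoxon_signed_rank", 0.0, 1.0, 0, exact=True, degenerate=True
        )
    ranks = _sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)
        pmf = _signed_rank_exact_sf(ranks2)
        w2 = int(round(2 * w_pos))
        p_le = pmf[: w2 + 1].sum()
        p_ge = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult("wilcoxon_signed_rank", w_pos, float(p), n, exact=True)
    mean = n * (n + 1) / 4.0
    # tie correction subtracts sum(t^3 - t)/48 from the null variance
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts**3 - counts).sum()) / 48.0
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
    p = 2.0 * _sps.norm.sf(abs(z))
    return TestResult("wilcoxon_signed_rank", w_pos, float(min(p, 1.0)), n, exact=False)


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of two samples.

    Exact when the pooled sample has at most 20 observations and no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    exact = (a.size + b.size <= EXACT_RANK_SUM_MAX_N) and no_ties
    res = _sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue),
        a.size + b.size, exact=exact,
    )


def bonferroni_level(alpha: float, m: int) -> float:
    """CI confidence level for ``m`` simultaneous intervals: ``1 - alpha/m``.

    E.g. alpha 0.05 over 8 components gives 0.99375.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return 1.0 - alpha / m
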