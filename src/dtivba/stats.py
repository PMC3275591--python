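"""Nonparametric-aware statistical layer for small two-group studies.

Three primitives, matching the analysis style of small-cohort animal
studies: a Shapiro-Francia W' normality test, a gated two-sample comparison
(Student's pooled-variance t when both samples look normal, otherwise the
Mann-Whitney U test with an exact small-sample p), and Spearman rank
correlation.  Missing values are removed pairwise; every result records
which method actually produced its p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "shapiro_francia",
    "mann_whitney",
    "two_sample_compare",
    "spearman",
    "describe",
]

#: Largest per-group size at which the Mann-Whitney p is computed by exact
#: enumeration of rank assignments (C(18, 9) = 48620 at the limit).
EXACT_MW_LIMIT = 9


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # shapiro_francia | t | mann_whitney_exact | mann_whitney_normal | spearman
    n_used: tuple[int, ...]
    note: str | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.statistic) and np.isfinite(self.p_value)


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x[np.isfinite(x)]


# ---------------------------------------------------------------------------
# Shapiro-Francia


def blom_scores(n: int) -> np.ndarray:
    """Expected standard-normal order statistics, Blom approximation."""
    i = np.arange(1, n + 1)
    return sps.norm.ppf((i - 3.0 / 8.0) / (n + 0.25))


def shapiro_francia(x) -> TestResult:
    """Shapiro-Francia W' test of normality.

    W' is the squared correlation between the sorted sample and the Blom
    scores; the p-value uses Royston's normal approximation of
    ``log(1 - W')`` (valid for 5 <= n <= 5000).
    """
    x = _clean(x)
    n = x.size
    if n < 5:
        raise ValueError(f"Shapiro-Francia needs n >= 5, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: W' undefined")
    m = blom_scores(n)
    xs = np.sort(x)
    w = float(np.corrcoef(xs, m)[0, 1] ** 2)
    u = np.log(n)
    v = np.log(u)
    mu = -1.2725 + 1.0521 * (v - u)
    sigma = 1.0308 - 0.26758 * (v + 2.0 / u)
    # W' can round to 1.0 for a perfectly linear QQ plot; p -> 1 then
    if w >= 1.0:
        return TestResult(1.0, 1.0, "shapiro_francia", (n,))
    z = (np.log(1.0 - w) - mu) / sigma
    p = float(sps.norm.sf(z))
    return TestResult(w, p, "shapiro_francia", (n,))


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _exact_mw_pvalue(ranks_x_sum: float, pooled_ranks: np.ndarray, n1: int) -> float:
    """Two-sided exact p by enumeration of all rank assignments.

    Uses a subset-sum dynamic program over the pooled midranks (doubled to
    integers), equivalent to full enumeration of the C(n, n1) group
    assignments, and handles ties through the midranks themselves.  The
    two-sided p is the probability of a rank-sum deviation from its mean at
    least as large as observed.
    """
    r2 = np.round(2 * pooled_ranks).astype(np.int64)  # midranks * 2 are integers
    total = int(r2.sum())
    n = r2.size
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(min(n1, n), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n1]
    sums = np.arange(total + 1)
    mean = n1 * total / n / 1.0
    obs_dev = abs(2 * ranks_x_sum - mean)
    extreme = counts[np.abs(sums - mean) >= obs_dev - 1e-9].sum()
    return float(extreme / counts.sum())


def mann_whitney(x, y, exact: bool | None = None, continuity: bool = True) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The p-value is exact (full enumeration of rank assignments, valid with
    ties) when both groups have at most ``EXACT_MW_LIMIT`` observations, and
    a tie-corrected normal approximation (with continuity correction)
    otherwise; ``exact`` forces one branch.  The reported statistic is
    ``U = min(U1, U2)``.
    """
    x, y = _clean(x), _clean(y)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    if exact is None:
        exact = max(n1, n2) <= EXACT_MW_LIMIT
    if exact:
        p = _exact_mw_pvalue(r1, ranks, n1)
        method = "mann_whitney_exact"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return TestResult(u, 1.0, "mann_whitney_normal", (n1, n2), note="all values tied")
        cc = 0.5 if continuity else 0.0
        z = (abs(u1 - n1 * n2 / 2.0) - cc) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(max(z, 0.0)))
        method = "mann_whitney_normal"
    return TestResult(u, min(p, 1.0), method, (n1, n2))


# ---------------------------------------------------------------------------
# gated two-sample comparison


def two_sample_compare(x, y, alpha_normality: float = 0.05) -> TestResult:
    """Student's t if both samples pass Shapiro-Francia, else Mann-Whitney.

    The pooled-variance two-sided t-test is used only when both samples pass
    the W' normality gate at ``alpha_normality`` (samples too small for the
    gate, n < 5, fall through to Mann-Whitney).  The chosen branch is in
    ``method``.
    """
    x, y = _clean(x), _clean(y)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 non-missing values per group")
    normal = False
    if x.size >= 5 and y.size >= 5 and np.ptp(x) > 0 and np.ptp(y) > 0:
        normal = (
            shapiro_francia(x).p_value > alpha_normality
            and shapiro_francia(y).p_value > alpha_normality
        )
    if normal:
        if np.ptp(np.concatenate([x, y])) == 0:
            return TestResult(0.0, 1.0, "t", (x.size, y.size), note="constant data")
        t, p = sps.ttest_ind(x, y, equal_var=True)
        return TestResult(float(t), float(p), "t", (x.size, y.size))
    return mann_whitney(x, y)


# ---------------------------------------------------------------------------
# Spearman


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the rank vectors; the two-sided p uses
    the t approximation ``t = rho * sqrt((n - 2) / (1 - rho^2))``.  Pairs
    with a missing value in either variable are dropped.  A constant vector
    yields an undefined (flagged) result rather than an error.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(np.nan, np.nan, "spearman", (n,), note="constant vector")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return TestResult(float(np.sign(rho)), 0.0, "spearman", (n,))
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return TestResult(rho, p, "spearman", (n,))


# ---------------------------------------------------------------------------
# descriptives


def describe(x, alpha_normality: float = 0.05) -> str:
    """``mean (sd)`` when the W' gate passes, else ``median (IQR)``."""
    x = _clean(x)
    if x.size == 0:
        return "n/a"
    normal = x.size >= 5 and np.ptp(x) > 0 and shapiro_francia(x).p_value > alpha_normality
    if normal:
        return f"{x.mean():.4g} ({x.std(ddof=1):.3g})"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.4g} ({q3 - q1:.3g})"
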