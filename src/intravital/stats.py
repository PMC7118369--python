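"""Statistical toolkit used by the pipeline reports.

Welch-corrected unpaired t test, paired t test, Mann-Whitney U (exact by
enumeration for small samples, normal approximation with tie correction
otherwise), and the standard error of the mean.  All p values are
two-sided.  Distribution functions come from scipy.stats; the test
statistics themselves are computed directly from their defining formulas
so the suite can cross-check them against independent oracles.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
from scipy import stats as sps

#: combined sample size at or below which Mann-Whitney p is exact
EXACT_MW_LIMIT = 12


@dataclasses.dataclass
class TestResult:
    """Outcome of a two-sample (or paired) hypothesis test."""

    statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str
    degrees_of_freedom: float | None = None
    degenerate: bool = False


def _as_sample(x, min_n: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def sem(values) -> float:
    """Standard error of the mean: sample sd (n-1 denominator) / sqrt(n)."""
    v = _as_sample(values, 2, "sem")
    return float(np.std(v, ddof=1) / np.sqrt(len(v)))


def welch_t(x, y) -> TestResult:
    """Unpaired t test with Welch's correction (unequal variances).

    t = (mean_x - mean_y) / sqrt(s1^2/n1 + s2^2/n2) with the
    Welch-Satterthwaite degrees of freedom; two-sided p from the t
    distribution.  Two zero-variance samples with equal means give
    t = 0, p = 1 (flagged degenerate); with unequal means the statistic
    is infinite and p is reported as 0 (flagged).
    """
    x = _as_sample(x, 2, "x")
    y = _as_sample(y, 2, "y")
    n1, n2 = len(x), len(y)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, n1, n2, "welch_t",
                              degrees_of_freedom=float(n1 + n2 - 2),
                              degenerate=True)
        t = math.inf if x.mean() > y.mean() else -math.inf
        return TestResult(t, 0.0, n1, n2, "welch_t", degenerate=True)
    t = float((x.mean() - y.mean()) / np.sqrt(se2))
    df = se2**2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(t, min(1.0, p), n1, n2, "welch_t",
                      degrees_of_freedom=float(df))


def paired_t(x, y) -> TestResult:
    """Paired t test: one-sample t on the pairwise differences."""
    x = _as_sample(x, 2, "x")
    y = _as_sample(y, 2, "y")
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = len(d)
    sd = np.std(d, ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TestResult(0.0, 1.0, n, n, "paired_t",
                              degrees_of_freedom=float(n - 1),
                              degenerate=True)
        t = math.inf if d.mean() > 0 else -math.inf
        return TestResult(t, 0.0, n, n, "paired_t",
                          degrees_of_freedom=float(n - 1), degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TestResult(t, min(1.0, p), n, n, "paired_t",
                      degrees_of_freedom=float(n - 1))


def _exact_mw_p(u1: float, n1: int, n2: int) -> float:
    """Exact two-sided p by full enumeration of rank assignments.

    Enumerates all C(n1+n2, n1) ways the x-sample can occupy ranks
    1..n1+n2 (valid when there are no ties), counts the null distribution
    of U, and doubles the smaller tail probability (capped at 1).
    """
    n = n1 + n2
    ranks = np.arange(1, n + 1)
    offset = n1 * (n1 + 1) / 2.0
    counts: dict[float, int] = {}
    total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        counts[u] = counts.get(u, 0) + 1
        total += 1
    u_min = min(u1, n1 * n2 - u1)
    tail = sum(c for u, c in counts.items() if u <= u_min)
    return min(1.0, 2.0 * tail / total)


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U test with midrank ties, two-sided.

    The statistic is U1 (for the first sample).  The p value is exact by
    enumeration when n1 + n2 <= 12 and there are no ties; otherwise it
    uses the normal approximation with tie correction and continuity
    correction.
    """
    x = _as_sample(x, 1, "x")
    y = _as_sample(y, 1, "y")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = float(r1 - n1 * (n1 + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    n = n1 + n2
    if n <= EXACT_MW_LIMIT and not has_ties:
        p = _exact_mw_p(u1, n1, n2)
        return TestResult(u1, p, n1, n2, "mann_whitney_u_exact")

    mu = n1 * n2 / 2.0
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all observations identical
        return TestResult(u1, 1.0, n1, n2, "mann_whitney_u_normal",
                          degenerate=True)
    # continuity correction toward the mean
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(u1, p, n1, n2, "mann_whitney_u_normal")


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality check, for reporting only.

    The pipeline does not gate test choice on this result; the caller
    decides which test fits the design.
    """
    v = _as_sample(values, 3, "values")
    stat, p = sps.shapiro(v)
    return TestResult(float(stat), float(p), len(v), 0, "shapiro_wilk")
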