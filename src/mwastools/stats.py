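"""Descriptive and follow-up statistics: Welch t, chi-squared independence,
and two-tailed Spearman correlation.

Conventions
-----------
* 2x2 chi-squared tables apply the Yates continuity correction by default;
  larger tables are never corrected.
* All p-values are two-sided (upper-tail for chi-squared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "welch_t", "chisq_independence", "spearman_corr"]

# smallest representable p; perfect correlations would otherwise give p == 0
_P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    df: float
    p: float
    method: str
    correction: bool = False
    estimate: float | None = None  # rho for Spearman, mean difference for Welch

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {self.p}")
        if self.df <= 0:
            raise ValueError(f"non-positive degrees of freedom: {self.df}")


def _welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch t requires n >= 2 in each group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("group standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    t = (mean2 - mean1) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(max(2.0 * sps.t.sf(abs(t), df), _P_FLOOR))
    return TestResult(
        statistic=float(t),
        df=float(df),
        p=p,
        method="welch-t",
        estimate=float(mean2 - mean1),
    )


def welch_t(*args) -> TestResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom.

    Two call forms:

    ``welch_t(mean1, sd1, n1, mean2, sd2, n2)``
        From summary statistics.
    ``welch_t(x, y)``
        From raw vectors; summary statistics are computed first (ddof=1),
        so both forms give identical results on the same data.
    """
    if len(args) == 6:
        return _welch_from_summary(*args)
    if len(args) == 2:
        x = np.asarray(args[0], dtype=float)
        y = np.asarray(args[1], dtype=float)
        return _welch_from_summary(
            x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
        )
    raise TypeError("welch_t takes (mean1, sd1, n1, mean2, sd2, n2) or (x, y)")


def chisq_independence(table, yates: bool = True) -> TestResult:
    """Pearson chi-squared test of independence for an r x c count table.

    The Yates 0.5 continuity correction is applied only when ``yates`` is
    true *and* the table is 2x2.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table entries must be non-negative integers")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")

    correct = bool(yates) and obs.shape == (2, 2)
    expected = sps.contingency.expected_freq(obs)
    diff = np.abs(obs - expected)
    if correct:
        diff = np.clip(diff - 0.5, 0.0, None)
    stat = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(max(sps.chi2.sf(stat, df), _P_FLOOR)) if stat > 0 else 1.0
    return TestResult(
        statistic=stat, df=float(df), p=p, method="chisq-independence",
        correction=correct,
    )


def spearman_corr(x, y) -> TestResult:
    """Two-tailed Spearman rank correlation (average ranks for ties).

    The p-value uses the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``
    on n-2 degrees of freedom; |rho| == 1 is clamped to the smallest
    representable p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no defined rank correlation")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = _P_FLOOR
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(max(2.0 * sps.t.sf(abs(t), n - 2), _P_FLOOR))
    return TestResult(
        statistic=rho, df=float(n - 2), p=p, method="spearman", estimate=rho
    )
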