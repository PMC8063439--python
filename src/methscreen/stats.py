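"""Statistical primitives shared by every screening stage.

Conventions used throughout the package:

* Spearman's rho is Pearson correlation on average ranks (ties -> mean rank);
  its two-sided p comes from the t approximation
  ``t = rho * sqrt((n - 2) / (1 - rho**2))``, with p = 0 at |rho| = 1.
  An exact permutation p-value is available for very small n.
* Benjamini-Hochberg adjustment is the classical step-up with monotone
  enforcement from the largest p, capped at 1, returned in input order.
* Fisher's exact test on 2x2 tables is two-sided by the point-probability
  rule (sum hypergeometric probabilities of tables at most as probable as the
  observed one, margins fixed); the odds ratio is the sample ratio ad/bc.
* The two-sample t test is pooled-variance Student by default, Welch optional.
* Survival uses the Kaplan-Meier product-limit estimator and the chi-square(1)
  log-rank test (both via lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "spearman",
    "pearson",
    "bh_adjust",
    "two_sample_t",
    "fisher_exact_2x2",
    "km_estimate",
    "logrank",
]


@dataclass
class TestResult:
    """A test statistic with its two-sided p-value and point estimate."""

    statistic: float
    p_value: float
    estimate: float | None = None
    n: int | None = None
    df: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y, method: str = "t") -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    Parameters
    ----------
    method
        ``"t"`` (default) uses the t approximation for any n; ``"exact"``
        enumerates all rank permutations (only allowed for n <= 9).
    """
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < 4:
        raise ValueError(f"spearman requires >= 4 complete pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranks; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    elif abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho * rho))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(statistic=rho, p_value=p, estimate=rho, n=n, df=n - 2, method="spearman")


def pearson(x, y) -> TestResult:
    """Product-moment correlation (replicate QC, doubling-time association)."""
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"pearson requires >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p), estimate=float(r), n=n, df=n - 2, method="pearson")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def two_sample_t(a, b, welch: bool = False) -> TestResult:
    """Two-sided two-sample t test (pooled-variance Student by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        raise ValueError("all values identical; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        estimate=float(np.mean(a) - np.mean(b)),
        n=len(a) + len(b),
        df=float(res.df),
        method="welch t" if welch else "student t",
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test; odds ratio ad/bc (inf when bc = 0)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(int)
    if t.sum() == 0:
        raise ValueError("table has no observations")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p), estimate=float(odds),
                      n=int(t.sum()), method="fisher exact")


def km_estimate(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit curve as (event time, survival) step pairs.

    The returned arrays start at (0, 1); censored times never drop the curve.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float)


def logrank(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    from lifelines.statistics import logrank_test

    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = logrank_test(times_a, times_b, event_observed_A=np.asarray(events_a, int),
                       event_observed_B=np.asarray(events_b, int))
    return TestResult(statistic=float(res.test_statistic), p_value=float(res.p_value),
                      n=len(times_a) + len(times_b), df=1.0, method="logrank")
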