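"""Statistical kernel: Fisher's exact test, Welch t, BH adjustment, quantile bins.

The two-sided Fisher test uses the probability-mass definition (sum over
tables, at fixed margins, whose probability does not exceed the observed
one) with all tail mass accumulated in log space, so p-values remain
accurate down past 1e-300 — contingency tables built from genome-scale
gene universes routinely produce such extremes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom
from scipy.stats import t as t_dist

__all__ = [
    "ContingencyResult",
    "fisher_exact",
    "expected_counts",
    "welch_t_test",
    "one_sample_t_test",
    "bh_adjust",
    "quantile_bins",
]

#: relative slack when comparing hypergeometric point masses, to make
#: floating-point ties behave like exact ties
_TIE_SLACK = 1e-7


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 table with independence expectations, Fisher p and odds ratio."""

    a: int
    b: int
    c: int
    d: int
    expected: tuple[tuple[float, float], tuple[float, float]]
    p_value: float
    odds_ratio: float
    odds_ratio_infinite: bool

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_dict(self) -> dict:
        return {
            "table": [[self.a, self.b], [self.c, self.d]],
            "expected": [list(r) for r in self.expected],
            "p_value": self.p_value,
            "odds_ratio": None if self.odds_ratio_infinite else self.odds_ratio,
            "odds_ratio_infinite": self.odds_ratio_infinite,
        }


def expected_counts(a: int, b: int, c: int, d: int):
    """Expected cell counts under row/column independence, e_ij = r_i c_j / N."""
    n = a + b + c + d
    r = (a + b, c + d)
    col = (a + c, b + d)
    return tuple(tuple(ri * cj / n for cj in col) for ri in r)


def _check_count(x, name):
    if not float(x).is_integer() or x < 0:
        raise ValueError(f"{name} must be a non-negative integer, got {x!r}")
    return int(x)


def fisher_exact(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher's exact test on the 2x2 table ((a, b), (c, d)).

    Conditional on the margins, the first cell follows a hypergeometric
    distribution; the two-sided p sums the point masses of all outcomes no
    more probable than the observed one (with a small relative slack for
    floating-point ties).  Sums are done in log space.
    """
    a, b, c, d = (_check_count(x, n) for x, n in zip((a, b, c, d), "abcd"))
    n = a + b + c + d
    if n < 1:
        raise ValueError("table must contain at least one observation")
    r1, c1 = a + b, a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n, c1, r1)
    obs = logpmf[a - lo]
    keep = logpmf <= obs + np.log1p(_TIE_SLACK)
    p = float(np.exp(logsumexp(logpmf[keep])))
    p = min(p, 1.0)
    infinite = b * c == 0 and a * d > 0
    odds = np.inf if infinite else (a * d / (b * c) if b * c else np.nan)
    return ContingencyResult(
        a, b, c, d, expected_counts(a, b, c, d), p, float(odds), bool(infinite)
    )


def welch_t_test(x, y):
    """Welch's unequal-variance t-test, two-tailed.

    Returns ``(p, t, df)`` with Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    sx, sy = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (x.size - 1) + sy**2 / (y.size - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(p), float(t), float(df)


def one_sample_t_test(x, mu: float = 0.0):
    """One-sample two-tailed t-test of mean(x) == mu; returns (p, t, df)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample (zero variance)")
    t = (x.mean() - mu) / (sd / np.sqrt(x.size))
    df = x.size - 1
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(p), float(t), float(df)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def quantile_bins(values, k: int = 7) -> np.ndarray:
    """Assign each value to one of ``k`` empirical quantile bins (0..k-1).

    Bin edges sit at the i/k empirical quantiles; a value equal to an edge
    goes to the lower bin.  With heavy ties several edges may coincide and
    bins can be unbalanced (a warning is emitted when all values are equal).
    """
    v = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if v.size < k:
        raise ValueError(f"need at least k={k} values, got {v.size}")
    edges = np.quantile(v, np.arange(1, k) / k)
    if edges[0] == edges[-1] and v.min() == v.max():
        warnings.warn("all values identical: every item falls in bin 0")
    # count of edges strictly below each value = bin index; ties -> lower bin
    return np.searchsorted(edges, v, side="left")
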