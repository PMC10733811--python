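"""Group-comparison statistics computable from printed summary data.

These are the sample-description and overall-performance statistics of a
two-group design: pooled and Welch two-sample t tests from (n, mean, sd)
summaries, the Yates-corrected chi-square for a 2x2 frequency table, and
the default two-sample Jeffreys–Zellner–Siow (JZS) Bayes factor computed
from a t statistic alone.  All operations are pure functions of summary
inputs; no raw data are required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "GroupSummary",
    "pooled_t",
    "welch_t",
    "yates_chi2",
    "jzs_bf_from_t",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group: size, mean, standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")


def pooled_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Classical pooled-variance two-sample t from summary statistics.

    Returns ``(t, df)`` with ``df = n_a + n_b - 2``.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    if se == 0.0:
        if a.mean == b.mean:
            return 0.0, float(df)
        raise ValueError("zero variance in both groups with unequal means")
    return (a.mean - b.mean) / se, float(df)


def welch_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Welch's unequal-variance t with Welch–Satterthwaite fractional df."""
    va = a.sd**2 / a.n
    vb = b.sd**2 / b.n
    se = math.sqrt(va + vb)
    if se == 0.0:
        if a.mean == b.mean:
            return 0.0, float(min(a.n, b.n) - 1)
        raise ValueError("zero variance in both groups with unequal means")
    t = (a.mean - b.mean) / se
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return t, df


def yates_chi2(table) -> float:
    """Pearson chi-square with Yates continuity correction on a 2x2 table.

    The correction subtracts 0.5 from each |observed - expected| deviation,
    clamped at zero so that a table exactly at its expected counts scores 0.
    Returns the statistic (df = 1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("table has a zero margin")
    expected = np.outer(row, col) / total
    dev = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    return float((dev**2 / expected).sum())


def jzs_bf_from_t(
    t: float,
    n1: int,
    n2: int,
    cauchy_scale: float = math.sqrt(2) / 2,
) -> float:
    """Default two-sample JZS Bayes factor BF10 from a t statistic.

    The effect size is given a zero-centred Cauchy prior with scale ``r``
    (default sqrt(2)/2), expressed as a scale mixture of normals with an
    inverse-gamma(1/2, r^2/2) mixing variable g.  BF10 is the ratio of the
    marginal likelihood of the data under that prior to the point-null
    likelihood, and depends on the data only through (t, n1, n2):

        BF10 = [ int_0^inf (1+N g)^(-1/2)
                 (1 + t^2 / ((1+N g) v))^(-(v+1)/2) pi(g) dg ]
               / (1 + t^2 / v)^(-(v+1)/2)

    with effective sample size N = n1 n2 / (n1 + n2) and df v = n1+n2-2.
    The integral is evaluated by adaptive quadrature.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if n1 < 2 or n2 < 2:
        raise ValueError("both group sizes must be at least 2")
    neff = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    r2 = cauchy_scale**2

    log_null = -(nu + 1) / 2 * math.log1p(t**2 / nu)

    def integrand(g: float) -> float:
        # inverse-gamma(1/2, r^2/2) density
        log_pi = (
            0.5 * math.log(r2 / 2)
            - special.gammaln(0.5)
            - 1.5 * math.log(g)
            - r2 / (2 * g)
        )
        log_lik = -0.5 * math.log1p(neff * g) - (nu + 1) / 2 * math.log1p(
            t**2 / ((1 + neff * g) * nu)
        )
        return math.exp(log_pi + log_lik - log_null)

    bf, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(bf)


def p_from_t(t: float, df: float) -> float:
    """Two-sided p-value of a t statistic (convenience for reports)."""
    return float(2 * stats.t.sf(abs(t), df))


def p_from_chi2(x2: float, df: int = 1) -> float:
    return float(stats.chi2.sf(x2, df))
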