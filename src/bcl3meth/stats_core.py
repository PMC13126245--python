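"""Shared statistical primitives.

Exact two-sided Fisher tests with odds ratios, Benjamini-Hochberg FDR,
Welch's t, Hedges' g with a normal-approximation confidence interval, and
pairwise sample correlations.  These back every enrichment and group
comparison in the pipeline, so they are kept small, explicit, and heavily
tested against independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "bh_fdr",
    "fisher_or",
    "welch_t",
    "hedges_g",
    "pairwise_corr",
]


@dataclass
class TestResult:
    """Outcome of a two-sample or contingency test.

    ``effect`` carries the odds ratio (Fisher) or the standardized mean
    difference (Hedges' g).  ``effect`` is ``inf`` when an odds ratio has an
    empty denominator with a nonzero numerator, and ``nan`` (with
    ``undefined=True``) when the ratio is 0/0.
    """

    statistic: float
    p: float
    effect: float
    df: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    undefined: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value outside [0,1]: {self.p}")
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValueError("ci_low exceeds ci_high")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_or(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test with the sample odds ratio ad/bc.

    The two-sided p-value sums hypergeometric probabilities of all tables
    (with the observed margins) whose probability does not exceed that of
    the observed table — the usual exact-test convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])

    ad, bc = a * d, b * c
    undefined = False
    if bc == 0:
        if ad == 0:
            effect = float("nan")
            undefined = True
        else:
            effect = float("inf")
    else:
        effect = ad / bc

    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0:
        return TestResult(statistic=float("nan"), p=1.0, effect=effect, undefined=True)

    # support of a given the margins
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    # tolerance guard against float noise when comparing equal-mass tables
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    p = min(1.0, p)
    return TestResult(statistic=float(a), p=p, effect=effect, undefined=undefined)


def _check_two_samples(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test with Satterthwaite df, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_two_samples(x, y)
    n1, n2 = x.size, y.size
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = x.mean() - y.mean()
    if se2 == 0:
        if diff == 0:
            return TestResult(statistic=0.0, p=1.0, effect=0.0, df=float(n1 + n2 - 2))
        raise ValueError("zero variance with unequal means: t undefined")
    t = diff / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=float(t), p=min(1.0, p), effect=float(diff), df=float(df))


def hedges_g(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Hedges' g: pooled-SD standardized difference with small-sample correction.

    Correction factor J = 1 - 3/(4(n1+n2) - 9).  The 95% CI uses the normal
    approximation of the standard error
    sqrt((n1+n2)/(n1*n2) + g^2 / (2(n1+n2-2))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_two_samples(x, y)
    n1, n2 = x.size, y.size
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    diff = x.mean() - y.mean()
    if pooled == 0:
        if diff == 0:
            return TestResult(statistic=0.0, p=1.0, effect=0.0, ci_low=0.0, ci_high=0.0)
        return TestResult(statistic=float("nan"), p=float("nan"), effect=float("nan"), undefined=True)
    d = diff / math.sqrt(pooled)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = j * d
    se = math.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2 - 2)))
    z = 1.959963984540054
    wt = welch_t(x, y)
    return TestResult(
        statistic=wt.statistic,
        p=wt.p,
        effect=float(g),
        df=wt.df,
        ci_low=float(g - z * se),
        ci_high=float(g + z * se),
    )


def pairwise_corr(beta: pd.DataFrame, pairs: Sequence[tuple[str, str]]) -> list[float]:
    """Pearson correlation over all shared CpGs for each sample-id pair.

    ``beta`` follows the package convention: rows are CpGs, columns samples.
    """
    out: list[float] = []
    for s1, s2 in pairs:
        for s in (s1, s2):
            if s not in beta.columns:
                raise ValueError(f"sample id not in matrix: {s}")
        a = beta[s1].to_numpy(dtype=float)
        b = beta[s2].to_numpy(dtype=float)
        out.append(float(np.corrcoef(a, b)[0, 1]))
    return out
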