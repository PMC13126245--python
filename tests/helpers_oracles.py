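"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths (and scipy's exact
tests): the Fisher oracle enumerates every table with the observed margins
using binomial coefficients, and the two-sample oracles spell out the
textbook formulas step by step.
"""

import math


def fisher_enumeration_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over fixed margins."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    denom = math.comb(n, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    probs = {}
    for x in range(lo, hi + 1):
        probs[x] = math.comb(r1, x) * math.comb(n - r1, c1 - x) / denom
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def welch_oracle(x: list, y: list) -> tuple:
    """(t, df) from the Welch formulas written out longhand."""
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - m2) ** 2 for yi in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def hedges_oracle(x: list, y: list) -> float:
    """Hedges' g = J * d with J = 1 - 3/(4(n1+n2) - 9)."""
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - m2) ** 2 for yi in y) / (n2 - 1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    d = (m1 - m2) / math.sqrt(pooled)
    return (1 - 3 / (4 * (n1 + n2) - 9)) * d


def pearson_oracle(x: list, y: list) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def iter_tables(max_margin: int):
    """All 2x2 count tables whose four margins are <= max_margin."""
    for r1 in range(max_margin + 1):
        for r2 in range(max_margin + 1):
            n = r1 + r2
            if n == 0:
                continue
            for c1 in range(max(0, n - max_margin), min(n, max_margin) + 1):
                lo = max(0, c1 - r2)
                hi = min(r1, c1)
                for a in range(lo, hi + 1):
                    yield a, r1 - a, c1 - a, r2 - (c1 - a)
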