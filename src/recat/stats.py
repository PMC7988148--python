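"""Statistical primitives used across the pipeline.

Spearman rank correlation (average ranks for ties, two-sided p via the
t-approximation), Benjamini-Hochberg step-up FDR adjustment, and Fisher's
exact test for 2x2 tables by full hypergeometric enumeration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

__all__ = ["spearman", "bh_adjust", "fisher_exact_2x2"]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p-value.

    Ties get average ranks; rho is the Pearson correlation of the rank
    vectors.  The p-value uses ``t = rho * sqrt((n-2)/(1-rho^2))`` on
    ``n - 2`` degrees of freedom; ``|rho| == 1`` maps to p = 0.  A
    zero-variance input yields ``(nan, nan)`` so callers can skip the pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman expects two equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValueError("spearman requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    rho = float(rx @ ry) / denom
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return (rho, 0.0)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return (rho, min(1.0, p))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` capped at 1, returned in the
    original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose probability is <= that of the observed
    table.  Ties are compared with a small *relative* tolerance: an
    absolute slack would wrongly sweep in every far-tail table once the
    observed pmf drops below it, inflating p for large tables.  The odds
    ratio is ``a*d / (b*c)``; a zero in ``b*c`` gives ``inf`` (or ``nan``
    when ``a*d`` is 0 too).
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    n = a + b + c + d
    if n == 0:
        return (odds, 1.0)
    row1, col1 = a + b, a + c
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = float(pmf[a - k_min])
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return (odds, min(1.0, p))
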