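"""Shared statistical primitives for site calling and differential tests.

The binomial upper tail underlies candidate m5C scoring: at a site with
coverage n and methylated depth k, the null is that every unconverted C is
bisulfite-conversion failure with probability p0 = 1 - conversion rate, so
p = P[X >= k] for X ~ Binomial(n, p0). Fisher's exact test (two-sided, by
hypergeometric enumeration) drives differential methylation, and a paired
Wilcoxon signed-rank test compares total vs polysome methylation levels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "binom_upper_tail",
    "adjust_bh",
    "fisher_exact_2x2",
    "paired_signed_rank",
]


def binom_upper_tail(k: int, n: int, p0: float) -> float:
    """P[X >= k] for X ~ Binomial(n, p0), by a log-space tail sum.

    Stable far into the tail (e.g. k = n = 20, p0 = 1e-3 gives 1e-60):
    terms are accumulated as logsumexp of exact log-pmf values rather than
    as 1 - CDF, which would underflow to 0 or lose all precision.
    """
    if not 0 <= p0 < 0.5:
        raise ValueError(f"p0 must be in [0, 0.5), got {p0}")
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"invalid (n={n}, k={k})")
    if k == 0:
        return 1.0
    if p0 == 0.0:
        return 0.0
    ks = np.arange(k, n + 1)
    return float(np.exp(logsumexp(sps.binom.logpmf(ks, n, p0))))


def binom_upper_tail_vec(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Vectorised :func:`binom_upper_tail` over aligned arrays."""
    if not 0 <= p0 < 0.5:
        raise ValueError(f"p0 must be in [0, 0.5), got {p0}")
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    out = np.ones(k.shape, dtype=float)
    pos = k > 0
    if p0 == 0.0:
        out[pos] = 0.0
        return out
    # unique (n, k) pairs keep the tail sums cheap on large pileups
    pairs, inv = np.unique(
        np.stack([n[pos], k[pos]], axis=1), axis=0, return_inverse=True
    )
    vals = np.array(
        [binom_upper_tail(int(kk), int(nn), p0) for nn, kk in pairs]
    )
    out[pos] = vals[inv]
    return out


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(table, tie_rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of non-negative counts.

    Sums hypergeometric probabilities over the support that do not exceed
    the observed table's probability, with a relative tolerance for
    floating-point ties. A table with any zero margin is uninformative and
    returns p = 1 by convention.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"table entries must be non-negative integers: {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + tie_rel_tol)].sum())
    return min(p, 1.0)


def paired_signed_rank(
    x, y, exact_max_n: int = 25
) -> dict[str, float]:
    """Wilcoxon signed-rank test on paired vectors ``x`` (e.g. total
    methylation levels) and ``y`` (e.g. polysome levels).

    Zero differences are dropped; tied |differences| receive average ranks.
    The exact null distribution is used up to ``exact_max_n`` non-zero
    pairs (when no ties are present); beyond that, a normal approximation
    with tie correction. Returns the statistic, two-sided p, the one-sided
    p for y > x, the number of pairs used and the median paired difference.
    All-zero differences give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = y - x
    nz = d[d != 0]
    n_used = nz.size
    if n_used == 0:
        return {
            "statistic": 0.0, "p_two_sided": 1.0, "p_greater": 1.0,
            "n_used": 0, "median_diff": 0.0,
        }
    ties = np.unique(np.abs(nz)).size < n_used
    method = "exact" if (n_used <= exact_max_n and not ties) else "approx"
    # continuity correction on the normal path, as in R's wilcox.test
    kwargs = {"correction": True} if method == "approx" else {}
    res_two = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                           method=method, **kwargs)
    res_gt = sps.wilcoxon(nz, zero_method="wilcox", alternative="greater",
                          method=method, **kwargs)
    return {
        "statistic": float(res_two.statistic),
        "p_two_sided": float(res_two.pvalue),
        "p_greater": float(res_gt.pvalue),
        "n_used": int(n_used),
        "median_diff": float(np.median(nz)),
    }
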