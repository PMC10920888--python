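"""Stratified 2x2 association: Mantel–Haenszel risk ratio and CMH test.

Each stratum is a 2x2 table over the patients hospitalized in one
(2-year window, age group, sex) cell::

                j present   j absent
    i present       a           b
    i absent        c           d

The pooled risk ratio is the Mantel–Haenszel estimator

    RR_MH = [sum_k a_k (c_k + d_k) / N_k] / [sum_k c_k (a_k + b_k) / N_k]

and independence is tested with the Cochran–Mantel–Haenszel chi-square
statistic (1 df, no continuity correction).  Everything is vectorized over
a leading axis of diagnosis pairs so that thousands of candidate pairs can
be screened at once; statsmodels' StratifiedTable serves as an independent
cross-check in the test-suite, not as the implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["mh_risk_ratio", "cmh_test", "cmh_pool"]


def _prep(a, b, c, d, mask):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if mask is None:
        mask = np.ones_like(a, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    return a, b, c, d, mask


def mh_risk_ratio(a, b, c, d, mask=None):
    """Mantel–Haenszel pooled risk ratio.

    Parameters are stratum cell counts, each of shape ``(K,)`` or
    ``(P, K)`` for P pairs by K strata; ``mask`` marks usable strata.
    Strata with N=0 or masked out contribute nothing.  A zero pooled
    denominator yields ``inf`` (flagged upstream), 0/0 yields ``nan``.
    """
    a, b, c, d, mask = _prep(a, b, c, d, mask)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(mask & (n > 0), 1.0 / n, 0.0)
        num = np.sum(a * (c + d) * w, axis=-1)
        den = np.sum(c * (a + b) * w, axis=-1)
        rr = np.where(den > 0, num / den, np.where(num > 0, np.inf, np.nan))
    return rr


def cmh_test(a, b, c, d, mask=None):
    """Cochran–Mantel–Haenszel chi-square statistic and two-sided p-value.

    ``stat = (sum_k a_k - sum_k E[a_k])^2 / sum_k Var[a_k]`` with the
    hypergeometric mean and variance per stratum, referred to chi2(1).
    Degenerate tables (zero total variance) give stat 0, p 1.
    """
    a, b, c, d, mask = _prep(a, b, c, d, mask)
    n = a + b + c + d
    ok = mask & (n > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(ok, (a + b) * (a + c) / n, 0.0)
        v = np.where(
            ok,
            (a + b) * (c + d) * (a + c) * (b + d) / (n * n * (n - 1)),
            0.0,
        )
    delta = np.sum(np.where(ok, a, 0.0) - e, axis=-1)
    var = np.sum(v, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, delta * delta / var, 0.0)
    return stat, stats.chi2.sf(stat, df=1)


def cmh_pool(strata):
    """Pool a list of usable :class:`ContingencyStratum`-like records.

    Accepts any iterable of objects with ``a, b, c, d`` attributes (or
    ``(a, b, c, d)`` tuples); returns ``(rr, p_value)``.
    """
    def cells(s):
        if hasattr(s, "a"):
            return s.a, s.b, s.c, s.d
        return tuple(s)

    arr = np.array([cells(s) for s in strata], dtype=float)
    if arr.size == 0:
        raise ValueError("cmh_pool needs at least one usable stratum")
    a, b, c, d = arr.T
    rr = mh_risk_ratio(a, b, c, d)
    _, p = cmh_test(a, b, c, d)
    return float(rr), float(p)
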