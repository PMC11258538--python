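"""Independent reference implementations used only by the test suite.

These are deliberately naive (readable, O(n^2), no acceleration tricks)
so they can serve as oracles for the production code paths.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def naive_lowess(y, frac: float, it: int) -> np.ndarray:
    """Cleveland's robust locally weighted regression, brute force, no delta.

    x is the sample index. At each point: tricube weights over the k
    nearest neighbors (k = int(frac*n)), weighted linear fit; then `it`
    robustifying passes with bisquare weights on residuals scaled by
    6 * median|residual|.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.arange(n, dtype=float)
    k = int(frac * n)
    k = max(k, 2)
    fitted = np.empty(n)
    robust_w = np.ones(n)
    for iteration in range(it + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            # window: k nearest neighbors (radius = k-th smallest distance)
            radius = np.sort(d)[k - 1]
            if radius <= 0:
                fitted[i] = y[i]
                continue
            u = np.clip(d / radius, 0.0, 1.0)
            w = (1.0 - u**3) ** 3
            w = w * robust_w
            sw = w.sum()
            if sw <= 0:
                fitted[i] = y[i]
                continue
            xm = (w * x).sum() / sw
            ym = (w * y).sum() / sw
            cov = (w * (x - xm) * (y - ym)).sum()
            var = (w * (x - xm) ** 2).sum()
            beta = cov / var if var > 0 else 0.0
            fitted[i] = ym + beta * (x[i] - xm)
        if iteration < it:
            resid = y - fitted
            s = np.median(np.abs(resid))
            if s == 0:
                robust_w = np.ones(n)
            else:
                u = np.clip(resid / (6.0 * s), -1.0, 1.0)
                robust_w = (1.0 - u**2) ** 2
    return fitted


def enumerate_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Each candidate table's probability is computed with the factorial
    formula r1! r2! c1! c2! / (N! a! b! c! d!) in exact rational
    arithmetic; the p-value sums tables whose probability is <= the
    observed table's (exact comparison, no float ties).
    """
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table")

    def prob(aa: int) -> Fraction:
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if min(bb, cc, dd) < 0:
            return Fraction(0)
        num = (
            math.factorial(r1)
            * math.factorial(r2)
            * math.factorial(c1)
            * math.factorial(c2)
        )
        den = (
            math.factorial(n)
            * math.factorial(aa)
            * math.factorial(bb)
            * math.factorial(cc)
            * math.factorial(dd)
        )
        return Fraction(num, den)

    p_obs = prob(a)
    total = Fraction(0)
    for aa in range(0, min(r1, c1) + 1):
        p = prob(aa)
        if p > 0 and p <= p_obs:
            total += p
    return float(total)


def rm_anova_reference(a: np.ndarray, b: np.ndarray):
    """Two-way repeated-measures ANOVA via statsmodels AnovaRM (least squares).

    `a`, `b`: subjects x timepoints matrices for the two conditions.
    Returns dict of (F, df1, df2) per effect.
    """
    import pandas as pd
    from statsmodels.stats.anova import AnovaRM

    n, T = a.shape
    rows = []
    for cond, mat in (("A", a), ("B", b)):
        for s in range(n):
            for t in range(T):
                rows.append({"subject": s, "cond": cond, "time": t, "y": mat[s, t]})
    df = pd.DataFrame(rows)
    res = AnovaRM(df, depvar="y", subject="subject", within=["cond", "time"]).fit()
    tab = res.anova_table
    out = {}
    mapping = {"cond": "trial_type", "time": "time", "cond:time": "interaction"}
    for key, name in mapping.items():
        row = tab.loc[key]
        out[name] = (
            float(row["F Value"]),
            int(row["Num DF"]),
            int(row["Den DF"]),
        )
    return out
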