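"""Independent reference implementations used to cross-check the estimators.

These are deliberately written along different paths from the package code:
scalar loops over the defining sums, statsmodels WLS for the Egger fit, and
an exhaustive scan of the cumulative-weight function for the weighted
median.  They exist only as oracles and are never imported by the package.
"""

from __future__ import annotations

import math

import numpy as np
import statsmodels.api as sm


def ivw_oracle(bx, sx, by, sy, random_effects=True):
    """Hand-coded weighted least squares through the origin, scalar loops."""
    num = den = 0.0
    for j in range(len(bx)):
        w = 1.0 / sy[j] ** 2
        num += w * bx[j] * by[j]
        den += w * bx[j] ** 2
    beta = num / den
    se = math.sqrt(1.0 / den)
    q = 0.0
    for j in range(len(bx)):
        q += (by[j] - beta * bx[j]) ** 2 / sy[j] ** 2
    if random_effects and len(bx) >= 2:
        se *= max(1.0, math.sqrt(q / (len(bx) - 1)))
    return beta, se, q


def egger_oracle(bx, sx, by, sy):
    """MR-Egger via statsmodels WLS with the same orientation and SE flooring."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    # statsmodels already scales SEs by sqrt(residual MSE); floor the scale at 1
    scale = math.sqrt(fit.scale)
    factor = 1.0 / scale if scale < 1.0 else 1.0
    intercept, slope = fit.params
    se_int, se_slope = fit.bse * factor
    return slope, se_slope, intercept, se_int


def weighted_median_oracle(theta, w):
    """Exhaustive interpolation of the cumulative-weight function at 0.5."""
    pairs = sorted(zip(theta, w))
    t = [p[0] for p in pairs]
    wn = [p[1] / sum(w) for p in pairs]
    cum = []
    acc = 0.0
    for wj in wn:
        cum.append(acc + wj / 2.0)
        acc += wj
    if 0.5 <= cum[0]:
        return t[0]
    if 0.5 >= cum[-1]:
        return t[-1]
    for j in range(len(t) - 1):
        if cum[j] <= 0.5 <= cum[j + 1]:
            frac = (0.5 - cum[j]) / (cum[j + 1] - cum[j])
            return t[j] + frac * (t[j + 1] - t[j])
    raise AssertionError("unreachable")


def clump_oracle(records, r2_lookup, r2_threshold, window_bp):
    """Greedy clumping re-stated with explicit pairwise loops.

    ``r2_lookup(a, b)`` returns the pairwise r² (0 when unknown).
    """
    remaining = sorted(records, key=lambda r: (r.pvalue, r.se, r.variant_id))
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for r in remaining:
            linked = (
                r.chromosome == index.chromosome
                and abs(r.position - index.position) <= window_bp
                and r2_lookup(r.variant_id, index.variant_id) > r2_threshold
            )
            if not linked:
                survivors.append(r)
        remaining = survivors
    return kept
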