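"""Independent reference implementations used only as test oracles.

Each oracle is coded separately from the library path it checks: the PMV
oracle transcribes the classic standard-annex BASIC algorithm (scaled
fixed-point iteration on t_cl/100), the clothing-temperature oracle is a
brute-force bisection on the heat-balance residual, the regression oracle
uses closed-form normal equations, and the rank-sum oracle enumerates the
permutation null directly from pairwise comparisons.
"""

from __future__ import annotations

import math
from itertools import combinations
from math import comb

import numpy as np


def iso_pmv(ta, tr, vel, rh_frac, met_wm2, clo, wme=0.0):
    """Classic standard-annex PMV algorithm (hundredths-scaled t_cl
    iteration, tolerance 1.5e-4 on the scaled variable)."""
    pa = rh_frac * 1000.0 * math.exp(16.6536 - 4030.183 / (ta + 235.0))
    icl = 0.155 * clo
    m = met_wm2
    mw = m - wme
    fcl = 1.05 + 0.645 * icl if icl > 0.078 else 1.0 + 1.29 * icl
    hcf = 12.1 * math.sqrt(vel)
    taa = ta + 273.0
    tra = tr + 273.0
    tcla = taa + (35.5 - ta) / (3.5 * icl + 0.1)
    p1 = icl * fcl
    p2 = p1 * 3.96
    p3 = p1 * 100.0
    p4 = p1 * taa
    p5 = 308.7 - 0.028 * mw + p2 * (tra / 100.0) ** 4
    xn = tcla / 100.0
    xf = tcla / 50.0
    n = 0
    hc = hcf
    # tolerance tightened below the standard's printed 1.5e-4 so the
    # oracle's own discretisation never dominates a comparison
    while abs(xn - xf) > 1e-8:
        xf = (xf + xn) / 2.0
        hcn = 2.38 * abs(100.0 * xf - taa) ** 0.25
        hc = hcf if hcf > hcn else hcn
        xn = (p5 + p4 * hc - p2 * xf**4) / (100.0 + p3 * hc)
        n += 1
        if n > 10000:
            raise RuntimeError("oracle iteration failed")
    tcl = 100.0 * xn - 273.0
    hl1 = 3.05e-3 * (5733.0 - 6.99 * mw - pa)
    hl2 = 0.42 * (mw - 58.15) if mw > 58.15 else 0.0
    hl3 = 1.7e-5 * m * (5867.0 - pa)
    hl4 = 0.0014 * m * (34.0 - ta)
    hl5 = 3.96 * fcl * (xn**4 - (tra / 100.0) ** 4)
    hl6 = fcl * hc * (tcl - ta)
    ts = 0.303 * math.exp(-0.036 * m) + 0.028
    return ts * (mw - hl1 - hl2 - hl3 - hl4 - hl5 - hl6)


def bisect_tcl(ta, tr, vel, met_wm2, clo, wme=0.0, tol=1e-8):
    """Brute-force bisection on the clothing-temperature residual
    g(t) = rhs(t) - t, which is strictly decreasing in t."""
    icl = 0.155 * clo
    fcl = 1.05 + 0.645 * icl if icl > 0.078 else 1.0 + 1.29 * icl
    mw = met_wm2 - wme

    def g(t):
        hc = max(2.38 * abs(t - ta) ** 0.25, 12.1 * math.sqrt(vel))
        rad = 3.96e-8 * fcl * ((t + 273.0) ** 4 - (tr + 273.0) ** 4)
        conv = fcl * hc * (t - ta)
        return 35.7 - 0.028 * mw - icl * (rad + conv) - t

    lo, hi = min(ta, tr) - 40.0, 90.0
    assert g(lo) > 0 > g(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ols_closed_form(y, x):
    """Normal-equations simple OLS: (slope, intercept, r_squared)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    syy = np.sum((y - y.mean()) ** 2)
    return slope, intercept, 1.0 - np.sum(resid**2) / syy


def perm_rank_sum_p(a, b):
    """Exhaustive two-sided permutation p-value for the rank-sum test via
    the Mann-Whitney U statistic counted directly from pairwise
    comparisons (ties count 1/2)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n, n_a = len(pooled), len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    mu = n_a * (n - n_a) / 2.0
    dev_obs = abs(u_stat(a, b) - mu)
    count = 0
    for idx in combinations(range(n), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        if abs(u_stat(ga, gb) - mu) >= dev_obs - 1e-12:
            count += 1
    return count / comb(n, n_a)
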