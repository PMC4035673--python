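"""Independent oracle implementations used only by the test suite.

These deliberately take different code paths from the package:
matrix normal equations instead of closed-form sums, brute-force
permutation enumeration instead of the inversion-count recursion.
"""

import itertools
import math

import numpy as np
from scipy import stats


def wls_oracle(y, x, w):
    """Simple weighted regression via matrix normal equations.

    Returns (slope, se_slope, t, p, df) and, for the intercept,
    (intercept, se_intercept, t0, p0).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    resid = y - X @ beta
    df = n - 2
    s2 = float(resid @ W @ resid) / df
    cov = s2 * np.linalg.inv(xtwx)
    out = []
    for j in (1, 0):
        se = math.sqrt(cov[j, j])
        t = beta[j] / se
        p = 2 * stats.t.sf(abs(t), df)
        out.append((float(beta[j]), se, float(t), float(p)))
    slope, se1, t1, p1 = out[0]
    intercept, se0, t0, p0 = out[1]
    return {
        "slope": slope, "se_slope": se1, "t": t1, "p": p1, "df": df,
        "intercept": intercept, "se_intercept": se0, "t0": t0, "p0": p0,
    }


def kendall_s(x, y):
    """Kendall's S by explicit pair counting."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    s = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        a = (x[j] > x[i]) - (x[j] < x[i])
        b = (y[j] > y[i]) - (y[j] < y[i])
        s += a * b
    return s


def begg_permutation_pvalue(x, y):
    """Two-sided exact p for Kendall's S by full permutation enumeration.

    Requires tie-free x and y; feasible for n <= 8.
    """
    n = len(x)
    pairs = list(itertools.combinations(range(n), 2))
    xf = [float(v) for v in x]
    xsign = {(i, j): (xf[j] > xf[i]) - (xf[j] < xf[i]) for i, j in pairs}
    s_obs = abs(kendall_s(x, y))
    hits = 0
    total = 0
    for perm in itertools.permutations([float(v) for v in y]):
        total += 1
        s = 0
        for i, j in pairs:
            s += xsign[(i, j)] * ((perm[j] > perm[i]) - (perm[j] < perm[i]))
        if abs(s) >= s_obs:
            hits += 1
    return hits / total


def begg_standardized_deviates_oracle(ln_dor, var):
    """Begg-Mazumdar deviates computed with numpy, independently."""
    t = np.asarray(ln_dor, dtype=float)
    v = np.asarray(var, dtype=float)
    w = 1.0 / v
    tbar = np.average(t, weights=w)
    vbar = 1.0 / w.sum()
    return (t - tbar) / np.sqrt(v - vbar)
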