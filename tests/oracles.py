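"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (sorting, double loops, closed forms,
textbook Newton-Raphson) and shares no code with the package.
"""

import numpy as np


def winsorize_by_sort(values, lower_pct=0.01, upper_pct=0.99):
    """Percentile capping via an explicit sort (numpy type-7 interpolation)."""
    v = np.asarray(values, dtype=float)
    s = np.sort(v)
    n = len(s)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    lo, hi = q(lower_pct), q(upper_pct)
    out = v.copy()
    out[out < lo] = lo
    out[out > hi] = hi
    return out


def ols_slope_intercept(x, y):
    """Closed-form simple OLS: slope = cov(x,y)/var(x)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    return y.mean() - slope * x.mean(), slope


def prs_double_loop(dosages, weights):
    """Naive per-participant, per-variant accumulation."""
    D = np.asarray(dosages, float)
    w = np.asarray(weights, float)
    n_var, n_part = D.shape
    out = np.zeros(n_part)
    for i in range(n_part):
        for v in range(n_var):
            out[i] += D[v, i] * w[v]
    return out


def column_moments_two_pass(M):
    """Mean and population SD per column, computed in two explicit passes."""
    M = np.asarray(M, float)
    means = np.array([sum(col) / len(col) for col in M.T])
    sds = np.array([np.sqrt(sum((col - m) ** 2) / len(col))
                    for col, m in zip(M.T, means)])
    return means, sds


def group_sizes_by_sort(values, n_strata):
    """Stratum sizes from explicitly sorted type-7 cut points.

    Mirrors the documented convention (linear-interpolation quantiles,
    boundary values assigned to the lower stratum) by manual arithmetic on
    the sorted sample.
    """
    v = np.asarray(values, dtype=float)
    s = np.sort(v)
    n = len(s)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    cuts = [q(k / n_strata) for k in range(1, n_strata)]
    sizes = []
    prev = -np.inf
    for c in cuts:
        sizes.append(int(np.sum((v > prev) & (v <= c))))
        prev = c
    sizes.append(int(np.sum(v > prev)))
    return sizes


def cox_newton(time, event, X, tol=1e-12, max_iter=50):
    """Textbook Newton-Raphson for the Cox partial likelihood (no ties).

    Assumes all event times are distinct, where Efron and Breslow weighting
    coincide; returns (beta, inverse information).
    """
    t = np.asarray(time, float)
    d = np.asarray(event, int)
    X = np.asarray(X, float)
    n, p = X.shape
    if len(np.unique(t[d == 1])) != d.sum():
        raise ValueError("oracle requires untied event times")
    beta = np.zeros(p)
    for _ in range(max_iter):
        grad = np.zeros(p)
        info = np.zeros((p, p))
        eta = X @ beta
        w = np.exp(eta)
        for i in np.where(d == 1)[0]:
            risk = t >= t[i]
            wr = w[risk]
            xr = X[risk]
            s0 = wr.sum()
            s1 = wr @ xr
            xbar = s1 / s0
            grad += X[i] - xbar
            s2 = (wr[:, None] * xr).T @ xr
            info += s2 / s0 - np.outer(xbar, xbar)
        step = np.linalg.solve(info, grad)
        beta = beta + step
        if np.abs(grad).max() < tol:
            break
    return beta, np.linalg.inv(info)


def reri_direct(hr10, hr01, hr11):
    return hr11 - hr10 - hr01 + 1.0, (hr11 - hr10 - hr01 + 1.0) / hr11
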