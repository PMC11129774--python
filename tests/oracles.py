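"""Independent brute-force oracles used only by the tests.

These deliberately take the naive route — explicit normal equations, and
exhaustive vertex enumeration for the spread linear program — so they share
no code path with the implementations they check.
"""

from itertools import combinations

import numpy as np


def ols_normal_equations(X, y):
    """OLS coefficients via an explicit Gram-matrix solve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.inv(X.T @ X) @ (X.T @ y)


def flr_spread_lp_vertex(X, y, centers, h=0.0):
    """Minimum-vagueness spreads by exhaustive vertex enumeration.

    Decision variables are ``s = (s^L_0..s^L_p, s^R_0..s^R_p)``.  Builds the
    full inequality system (inclusion constraints at level h plus
    non-negativity), enumerates every choice of ``2(p+1)`` active
    constraints, solves the square system, keeps feasible points, and
    returns the objective-minimizing one.

    Returns ``(s_left, s_right, objective)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    centers = np.asarray(centers, dtype=float)
    n, m = X.shape
    absX = np.abs(X)
    resid = y - X @ centers
    shrink = 1.0 - h
    nvar = 2 * m
    cost = np.concatenate([absX.sum(axis=0)] * 2)

    # G s <= g
    rows = []
    rhs = []
    zeros = np.zeros(m)
    for i in range(n):
        rows.append(np.concatenate([-shrink * absX[i], zeros]))
        rhs.append(resid[i])
        rows.append(np.concatenate([zeros, -shrink * absX[i]]))
        rhs.append(-resid[i])
    for k in range(nvar):
        e = np.zeros(nvar)
        e[k] = -1.0
        rows.append(e)
        rhs.append(0.0)
    G = np.array(rows)
    g = np.array(rhs)

    best = None
    best_obj = np.inf
    for active in combinations(range(len(G)), nvar):
        A = G[list(active)]
        b = g[list(active)]
        try:
            s = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if np.all(G @ s <= g + 1e-9):
            obj = cost @ s
            if obj < best_obj - 1e-12:
                best_obj = obj
                best = s
    assert best is not None, "LP oracle found no feasible vertex"
    return best[:m], best[m:], float(best_obj)
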