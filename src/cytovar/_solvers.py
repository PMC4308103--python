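"""Numba kernels: lasso coordinate descent and the hierarchy-constrained QP.

These are hot paths — the resampling harness calls them hundreds of thousands
of times — so they are jitted and operate on bare arrays.  The public modules
wrap them with validation, standardization and dataclass results.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=False)
def lasso_cd(X, y, lam, beta, tol, max_iter):
    """Coordinate descent for ``RSS + lam * sum(|beta_j|)``.

    ``beta`` is modified in place (warm start).  Returns the iteration count,
    or -1 if the coefficient-change tolerance was not reached.
    Exact zeros come from the soft-threshold operator itself.
    """
    n, p = X.shape
    g = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        g[j] = s
    r = y.copy()
    for i in range(n):
        for j in range(p):
            r[i] -= X[i, j] * beta[j]
    thr = lam / 2.0
    for it in range(max_iter):
        delta = 0.0
        for j in range(p):
            rho = 0.0
            for i in range(n):
                rho += X[i, j] * r[i]
            rho += g[j] * beta[j]
            bj = soft_threshold(rho, thr) / g[j]
            d = bj - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
                beta[j] = bj
            if abs(d) > delta:
                delta = abs(d)
        if delta < tol:
            return it + 1
    return -1


@njit(cache=False)
def lasso_cd_path(X, y, lambdas, tol, max_iter):
    """Warm-started coordinate descent along a decreasing lambda grid."""
    p = X.shape[1]
    m = lambdas.shape[0]
    betas = np.zeros((m, p))
    beta = np.zeros(p)
    status = np.zeros(m, dtype=np.int64)
    for k in range(m):
        status[k] = lasso_cd(X, y, lambdas[k], beta, tol, max_iter)
        for j in range(p):
            betas[k, j] = beta[j]
    return betas, status


# ---------------------------------------------------------------------------
# Strong-hierarchy interaction lasso, p = 2.
#
# Split-variable convex program (Bien-style):
#   u = (b1p, b1m, b2p, b2m, tp, tm) >= 0,  beta_j = bjp - bjm,  theta = tp - tm
#   minimise 0.5*||y - Z u||^2 + lam * sum(u)
#   s.t.  tp + tm <= b1p + b1m   and   tp + tm <= b2p + b2m
# with Z = [x1, -x1, x2, -x2, x12, -x12] (columns centred/scaled upstream).
# The constraint is the convex surrogate of strong hierarchy
# (theta != 0 only if both main effects carry mass).
# ---------------------------------------------------------------------------


@njit(cache=False)
def _T(v4, v5, mu):
    return max(v4 - mu, 0.0) + max(v5 - mu, 0.0)


@njit(cache=False)
def _B(va, vb, mu):
    return max(va + mu, 0.0) + max(vb + mu, 0.0)


@njit(cache=False)
def _inv_B(va, vb, s):
    """Real mu with _B(va, vb, mu) == s (smallest such mu when flat)."""
    hi = max(va, vb)
    lo = min(va, vb)
    if s <= 0.0:
        return -hi
    if s >= hi - lo:
        return (s - va - vb) / 2.0
    return s - hi


@njit(cache=False)
def _bisect_single(v4, v5, va, vb, lohi):
    """Root of T(mu) - B(mu) on [0, lohi] (T decreasing, B increasing)."""
    lo = 0.0
    hi = lohi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _T(v4, v5, mid) - _B(va, vb, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=False)
def project_hier(v):
    """Euclidean projection of v in R^6 onto the constraint set above.

    Boundary ties are resolved to exact zeros: coordinates whose projected
    value is below machine-level tolerance (relative to ``v``) are bisection
    residue at a clamp corner, not signal, and are snapped inside the
    operator so the active set is exact.
    """
    u = _project_hier_raw(v)
    vmax = 0.0
    for k in range(6):
        if abs(v[k]) > vmax:
            vmax = abs(v[k])
    snap = 1e-13 * (1.0 + vmax)
    if u[4] < snap:
        u[4] = 0.0
    if u[5] < snap:
        u[5] = 0.0
    if u[4] == 0.0 and u[5] == 0.0:
        for k in range(4):
            if u[k] < snap:
                u[k] = 0.0
    return u


@njit(cache=False)
def _project_hier_raw(v):
    u = np.empty(6)
    tol = 1e-12
    # case 0: coupling constraints slack
    for k in range(6):
        u[k] = max(v[k], 0.0)
    T0 = u[4] + u[5]
    if T0 <= u[0] + u[1] + tol and T0 <= u[2] + u[3] + tol:
        return u
    mu_hi = max(max(v[4], v[5]), 0.0) + 1.0

    # case a: only constraint 1 active
    if T0 > u[0] + u[1]:
        mu1 = _bisect_single(v[4], v[5], v[0], v[1], mu_hi)
        if mu1 >= -tol and _T(v[4], v[5], mu1) <= _B(v[2], v[3], 0.0) + 1e-9:
            u[0] = max(v[0] + mu1, 0.0)
            u[1] = max(v[1] + mu1, 0.0)
            u[2] = max(v[2], 0.0)
            u[3] = max(v[3], 0.0)
            u[4] = max(v[4] - mu1, 0.0)
            u[5] = max(v[5] - mu1, 0.0)
            return u
    # case b: only constraint 2 active
    if T0 > u[2] + u[3]:
        mu2 = _bisect_single(v[4], v[5], v[2], v[3], mu_hi)
        if mu2 >= -tol and _T(v[4], v[5], mu2) <= _B(v[0], v[1], 0.0) + 1e-9:
            u[0] = max(v[0], 0.0)
            u[1] = max(v[1], 0.0)
            u[2] = max(v[2] + mu2, 0.0)
            u[3] = max(v[3] + mu2, 0.0)
            u[4] = max(v[4] - mu2, 0.0)
            u[5] = max(v[5] - mu2, 0.0)
            return u
    # case c: both active; bisect on mu = mu1 + mu2 using
    # F(mu) = invB1(T(mu)) + invB2(T(mu)) - mu (strictly decreasing).
    # The bracket must cover degenerate corners where B stays 0 (all-negative
    # main-effect coordinates), hence the extra -min(v) terms.
    lo = 0.0
    hi = mu_hi + max(-max(v[0], v[1]), 0.0) + max(-max(v[2], v[3]), 0.0) + 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        t = _T(v[4], v[5], mid)
        f = _inv_B(v[0], v[1], t) + _inv_B(v[2], v[3], t) - mid
        if f > 0.0:
            lo = mid
        else:
            hi = mid
    mu = 0.5 * (lo + hi)
    t = _T(v[4], v[5], mu)
    mu1 = max(_inv_B(v[0], v[1], t), 0.0)
    mu2 = max(_inv_B(v[2], v[3], t), 0.0)
    u[0] = max(v[0] + mu1, 0.0)
    u[1] = max(v[1] + mu1, 0.0)
    u[2] = max(v[2] + mu2, 0.0)
    u[3] = max(v[3] + mu2, 0.0)
    u[4] = max(v[4] - mu1 - mu2, 0.0)
    u[5] = max(v[5] - mu1 - mu2, 0.0)
    return u


@njit(cache=False)
def hier_fista(G, c, lam, step, u0, tol, max_iter):
    """Accelerated projected proximal gradient for the split-variable QP.

    Smooth part: 0.5 u'Gu - c'u (== 0.5||y - Zu||^2 up to a constant);
    the linear penalty lam*sum(u) folds into the gradient step; the
    constraint set is handled by exact projection.  Returns (u, iterations)
    with iterations == -1 on non-convergence.
    """
    u = u0.copy()
    z = u0.copy()
    tk = 1.0
    grad = np.empty(6)
    for it in range(max_iter):
        for a in range(6):
            s = lam
            for b in range(6):
                s += G[a, b] * z[b]
            grad[a] = s - c[a]
        w = np.empty(6)
        for a in range(6):
            w[a] = z[a] - step * grad[a]
        u_new = project_hier(w)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        delta = 0.0
        for a in range(6):
            z[a] = u_new[a] + ((tk - 1.0) / t_new) * (u_new[a] - u[a])
            d = abs(u_new[a] - u[a])
            if d > delta:
                delta = d
            u[a] = u_new[a]
        tk = t_new
        if delta < tol:
            return u, it + 1
    return u, -1
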