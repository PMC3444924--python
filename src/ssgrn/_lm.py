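"""Compiled Levenberg-Marquardt routines for the lower-level fit.

The bi-level search evaluates tens of thousands of candidate topologies,
each requiring a nonlinear least-squares fit whose every residual
evaluation integrates the S-system ODEs.  These routines keep the entire
fit — RK4 integration, forward-difference Jacobian, damped normal
equations, bound clipping — inside numba-compiled code.

Bounds are handled by projection: proposed steps are clipped to the box,
and Jacobian difference steps are taken inward at an active bound.  The
Marquardt damping uses diagonal scaling, so the step interpolates between
Gauss-Newton and scaled gradient descent.
"""

from __future__ import annotations

import numpy as np

from .ssystem import _rk4_kernel, njit


@njit(cache=True)
def _traj_chi(theta, rows, cols, n, x0, grid, Y, substeps, ceiling, floor):  # pragma: no cover
    """Residual vector of the trajectory fit; ok=False flags divergence."""
    G = np.zeros((n, n))
    for e in range(rows.shape[0]):
        G[rows[e], cols[e]] = theta[2 * n + e]
    values, ok = _rk4_kernel(theta[:n], theta[n : 2 * n], G, x0, grid, substeps, ceiling, floor)
    m = Y.shape[0]
    r = np.empty(m * n)
    if not ok:
        return r, False
    for t in range(m):
        for i in range(n):
            r[t * n + i] = values[t, i] - Y[t, i]
    return r, True


@njit(cache=True)
def _lm_traj(theta0, rows, cols, x0, grid, Y, substeps, ceiling, floor, lo, hi, max_iter, tol_hint):  # pragma: no cover
    """Box-clipped Levenberg-Marquardt on the trajectory residual.

    Returns (theta, chi); chi = inf when the start point already diverges
    and no progress can be made.  ``tol_hint`` (the feasibility tolerance)
    steers the stopping rule: candidates far above it stop once progress
    per iteration is fractions of a percent, while near-feasible candidates
    are driven to full precision.
    """
    n = x0.shape[0]
    p = theta0.shape[0]
    N = Y.size
    theta = np.minimum(np.maximum(theta0, lo), hi)
    r, ok = _traj_chi(theta, rows, cols, n, x0, grid, Y, substeps, ceiling, floor)
    if not ok:
        return theta, np.inf
    cost = 0.5 * (r @ r)
    damp = 1e-3
    stall = 0
    J = np.empty((N, p))
    for _it in range(max_iter):
        # forward-difference Jacobian, stepping inward at active bounds
        for k in range(p):
            h = 1e-6 * max(abs(theta[k]), 1e-3)
            if theta[k] + h > hi[k]:
                h = -h
            tk = theta[k]
            theta[k] = tk + h
            rk, okk = _traj_chi(theta, rows, cols, n, x0, grid, Y, substeps, ceiling, floor)
            theta[k] = tk
            if not okk:
                h = -h
                theta[k] = tk + h
                rk, okk = _traj_chi(theta, rows, cols, n, x0, grid, Y, substeps, ceiling, floor)
                theta[k] = tk
            if okk:
                for q in range(N):
                    J[q, k] = (rk[q] - r[q]) / h
            else:
                for q in range(N):
                    J[q, k] = 0.0
        A = J.T @ J
        g = J.T @ r
        improved = False
        for _try in range(12):
            Ad = A.copy()
            for k in range(p):
                dk = A[k, k]
                if dk < 1e-10:
                    dk = 1e-10
                Ad[k, k] = A[k, k] + damp * dk
            delta = np.linalg.solve(Ad, -g)
            theta_new = np.minimum(np.maximum(theta + delta, lo), hi)
            r_new, okn = _traj_chi(theta_new, rows, cols, n, x0, grid, Y, substeps, ceiling, floor)
            if okn:
                cost_new = 0.5 * (r_new @ r_new)
                if cost_new < cost:
                    rel = (cost - cost_new) / max(cost, 1e-300)
                    theta = theta_new
                    r = r_new
                    cost = cost_new
                    damp = max(damp * 0.25, 1e-12)
                    improved = True
                    if rel < 1e-9:
                        return theta, np.sqrt(2.0 * cost)
                    # infeasible candidates whose progress has stalled for
                    # several iterations need only a ranking-quality chi,
                    # not a machine-precision one
                    if rel < 1e-4:
                        stall += 1
                        if stall >= 3 and cost > 2.0 * tol_hint * tol_hint:
                            return theta, np.sqrt(2.0 * cost)
                    else:
                        stall = 0
                    break
            damp *= 4.0
            if damp > 1e10:
                break
        if not improved:
            break
    return theta, np.sqrt(2.0 * cost)


@njit(cache=True)
def _slope_resid(theta, L, y, dy):  # pragma: no cover
    """Algebraic rate-law residual  a*prod(x^rho) - b*x - dx/dt  per time point."""
    m = y.shape[0]
    k = L.shape[1]
    r = np.empty(m)
    for t in range(m):
        s = 0.0
        for q in range(k):
            s += L[t, q] * theta[2 + q]
        r[t] = theta[0] * np.exp(s) - theta[1] * y[t] - dy[t]
    return r


@njit(cache=True)
def _lm_slope(theta0, L, y, dy, lo, hi, max_iter):  # pragma: no cover
    """Levenberg-Marquardt on the decoupled slope-matching residual.

    Returns (theta, cost); run from several starts and keep the best — the
    decoupled landscape has degenerate bound-hugging local minima.
    """
    p = theta0.shape[0]
    m = y.shape[0]
    theta = np.minimum(np.maximum(theta0, lo), hi)
    r = _slope_resid(theta, L, y, dy)
    cost = 0.5 * (r @ r)
    damp = 1e-3
    J = np.empty((m, p))
    for _it in range(max_iter):
        for k in range(p):
            h = 1e-6 * max(abs(theta[k]), 1e-3)
            if theta[k] + h > hi[k]:
                h = -h
            tk = theta[k]
            theta[k] = tk + h
            rk = _slope_resid(theta, L, y, dy)
            theta[k] = tk
            for q in range(m):
                J[q, k] = (rk[q] - r[q]) / h
        A = J.T @ J
        g = J.T @ r
        improved = False
        for _try in range(12):
            Ad = A.copy()
            for k in range(p):
                dk = A[k, k]
                if dk < 1e-10:
                    dk = 1e-10
                Ad[k, k] = A[k, k] + damp * dk
            delta = np.linalg.solve(Ad, -g)
            theta_new = np.minimum(np.maximum(theta + delta, lo), hi)
            r_new = _slope_resid(theta_new, L, y, dy)
            cost_new = 0.5 * (r_new @ r_new)
            if cost_new < cost:
                rel = (cost - cost_new) / max(cost, 1e-300)
                theta = theta_new
                r = r_new
                cost = cost_new
                damp = max(damp * 0.25, 1e-12)
                improved = True
                if rel < 1e-9:
                    return theta, cost
                break
            damp *= 4.0
            if damp > 1e10:
                break
        if not improved:
            break
    return theta, cost
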