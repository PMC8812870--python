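"""Numba kernel: IRLS + cyclic coordinate descent for penalized logistic fits.

Maximizes the penalized binomial log-likelihood

    l(b0, beta) - sum_j nu_j * [ xi |beta_j| + ((1 - xi)/2) beta_j^2 ]

on a standardized design by iteratively reweighted least squares, with the
quadratic subproblem solved by cyclic soft-thresholding updates and a
glmnet-style active-set strategy.  The intercept is unpenalized.  IRLS weights
are floored for numerical stability.
"""

import numpy as np
from numba import njit

# status codes returned by irls_cd
OK = 0
NOT_CONVERGED = 1
NONFINITE = 2


@njit(cache=True, fastmath=False)
def _cd_sweep(Xt, r, eta, w, xw_sq, sw, nu, xi, b0, beta, active_only, active):
    """One cyclic sweep; returns (b0, max_abs_change)."""
    J, N = Xt.shape
    maxd = 0.0
    # intercept first
    num0 = 0.0
    for i in range(N):
        num0 += w[i] * r[i]
    d0 = num0 / sw
    if d0 != 0.0:
        b0 += d0
        for i in range(N):
            r[i] -= d0
            eta[i] += d0
    if abs(d0) > maxd:
        maxd = abs(d0)
    for j in range(J):
        if active_only and not active[j]:
            continue
        denom = xw_sq[j] + (1.0 - xi) * nu[j]
        if xw_sq[j] <= 0.0:
            # constant (zero) column: coefficient pinned at 0
            if beta[j] != 0.0:
                d = -beta[j]
                beta[j] = 0.0
                for i in range(N):
                    r[i] -= d * Xt[j, i]
                    eta[i] += d * Xt[j, i]
                if abs(d) > maxd:
                    maxd = abs(d)
            continue
        num = xw_sq[j] * beta[j]
        for i in range(N):
            num += w[i] * Xt[j, i] * r[i]
        thr = xi * nu[j]
        if num > thr:
            bnew = (num - thr) / denom
        elif num < -thr:
            bnew = (num + thr) / denom
        else:
            bnew = 0.0
        d = bnew - beta[j]
        if d != 0.0:
            beta[j] = bnew
            for i in range(N):
                r[i] -= d * Xt[j, i]
                eta[i] += d * Xt[j, i]
            if abs(d) > maxd:
                maxd = abs(d)
        active[j] = beta[j] != 0.0
    return b0, maxd


@njit(cache=True, fastmath=False)
def irls_cd(Xt, y, nu, xi, b0, beta, cd_tol, cd_max_iter, irls_max_iter, w_floor):
    """Fit the penalized logistic regression; modifies ``beta`` in place.

    Parameters
    ----------
    Xt : (J, N) C-contiguous standardized design, transposed.
    y : (N,) 0/1 outcomes.
    nu : (J,) per-coefficient penalty multipliers (>= 0).
    xi : elastic-net mixture weight in [0, 1].
    b0, beta : warm-start intercept and coefficients (standardized scale).

    Returns
    -------
    (b0, n_sweeps, status)
    """
    J, N = Xt.shape
    eta = np.empty(N)
    for i in range(N):
        s = b0
        for j in range(J):
            if beta[j] != 0.0:
                s += Xt[j, i] * beta[j]
        eta[i] = s
    active = np.empty(J, dtype=np.bool_)
    for j in range(J):
        active[j] = beta[j] != 0.0
    w = np.empty(N)
    r = np.empty(N)
    xw_sq = np.empty(J)
    n_sweeps = 0
    status = NOT_CONVERGED
    for _outer in range(irls_max_iter):
        # quadratic approximation at the current (b0, beta)
        sw = 0.0
        ok = True
        for i in range(N):
            e = eta[i]
            if not np.isfinite(e):
                ok = False
                break
            mu = 1.0 / (1.0 + np.exp(-e))
            wi = mu * (1.0 - mu)
            if wi < w_floor:
                wi = w_floor
            w[i] = wi
            sw += wi
            r[i] = (y[i] - mu) / wi  # r = z - eta with working response z
        if not ok:
            return b0, n_sweeps, NONFINITE
        for j in range(J):
            s = 0.0
            for i in range(N):
                s += w[i] * Xt[j, i] * Xt[j, i]
            xw_sq[j] = s
        b0_start = b0
        beta_change = 0.0
        # inner CD: full sweep, then active-set sweeps, then a confirming full sweep
        inner_done = False
        while not inner_done and n_sweeps < cd_max_iter:
            b0, maxd = _cd_sweep(
                Xt, r, eta, w, xw_sq, sw, nu, xi, b0, beta, False, active
            )
            n_sweeps += 1
            if maxd > beta_change:
                beta_change = maxd
            if maxd < cd_tol:
                inner_done = True
                break
            while n_sweeps < cd_max_iter:
                b0, maxd = _cd_sweep(
                    Xt, r, eta, w, xw_sq, sw, nu, xi, b0, beta, True, active
                )
                n_sweeps += 1
                if maxd > beta_change:
                    beta_change = maxd
                if maxd < cd_tol:
                    break
        # eta drifted from z - r bookkeeping only through updates; it is exact.
        d_outer = beta_change if beta_change > abs(b0 - b0_start) else abs(b0 - b0_start)
        if d_outer < cd_tol:
            status = OK
            break
    return b0, n_sweeps, status
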