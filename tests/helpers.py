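"""Independent numerical oracles used to cross-check the package's solvers."""

import numpy as np
from scipy.special import expit


def fista_penalized_logistic(Xs, y, nu, xi, n_iter=200_000, tol=1e-12):
    """Proximal-gradient (FISTA) maximizer of the penalized logistic likelihood.

    Same objective as the coordinate-descent M-step: total log-likelihood
    minus sum_j nu_j (xi |b_j| + (1-xi)/2 b_j^2), intercept unpenalized.
    Deliberately a different algorithm from the implementation under test.
    """
    n, j = Xs.shape
    nu = np.broadcast_to(np.asarray(nu, float), (j,))
    Z = np.column_stack([np.ones(n), Xs])
    lip = 0.25 * np.linalg.norm(Z, 2) ** 2 + (1 - xi) * nu.max()
    w = np.zeros(j + 1)
    v = w.copy()
    t = 1.0
    for _ in range(n_iter):
        eta = Z @ v
        grad = Z.T @ (y - expit(eta))  # gradient of log-likelihood
        grad[1:] -= (1 - xi) * nu * v[1:]
        w_new = v + grad / lip
        thresh = xi * nu / lip
        w_new[1:] = np.sign(w_new[1:]) * np.maximum(np.abs(w_new[1:]) - thresh, 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        v = w_new + ((t - 1) / t_new) * (w_new - w)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w, t = w_new, t_new
    return w[0], w[1:]


def penalized_objective(Xs, y, b0, beta, nu, xi):
    eta = b0 + Xs @ beta
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    nu = np.broadcast_to(np.asarray(nu, float), beta.shape)
    return ll - np.sum(nu * (xi * np.abs(beta) + 0.5 * (1 - xi) * beta**2))


def golden_section_1d(f, lo, hi, tol=1e-12):
    """Golden-section maximizer of a unimodal scalar function."""
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    while abs(b - a) > tol:
        if f(c) > f(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    return 0.5 * (a + b)


def auc_brute_force(y, p):
    """Pairwise Mann-Whitney count: concordant pairs + half ties."""
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
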