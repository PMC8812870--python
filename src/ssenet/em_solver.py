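"""EM coordinate descent fitting of the six model variants.

Fits lasso / elastic net (single penalized run) and their spike-and-slab
counterparts with or without IAR-smoothed inclusion priors (SSL, SSEN,
SSL-IAR, SSEN-IAR) by alternating:

  E-step   p_j  = posterior slab probability given beta_j, theta_j
           nu_j = expected inverse scale  p_j/s1 + (1 - p_j)/s0
  M-step   (b0, beta) <- coordinate-descent solution of the penalized
           logistic likelihood with per-coefficient penalties nu_j;
           theta    <- IAR update over the adjacency graph (spatial) or the
           shared mean of p (non-spatial)

until the coefficients stabilize.  Predictors are standardized internally
(mean 0, population sd 1); coefficients are reported on the original scale.
The intercept is always present and never penalized.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from . import _cd
from .spatial_graph import AdjacencyGraph, InclusionField, iar_update, PSI_BOUND
from .ssen_prior import (
    PriorSpec,
    e_step_inclusion,
    effective_inverse_scale,
    en_log_density,
)

logger = logging.getLogger(__name__)

_THETA_EPS = 1e-6  # keeps the shared-theta update strictly inside (0, 1)


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class DesignData:
    """Validated subjects-by-predictors design with a binary outcome.

    ``X`` is kept on the original scale; ``standardized()`` returns the
    column-standardized matrix (population sd).  Constant columns get scale 1
    and are flagged; their standardized values are exactly zero, which pins
    their coefficients at zero during fitting.
    """

    X: np.ndarray
    y: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    constant_mask: np.ndarray
    _X_std: np.ndarray | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_arrays(cls, X, y) -> "DesignData":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (subjects x predictors)")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values")
        yvals = np.unique(y)
        if not np.all(np.isin(yvals, [0, 1])):
            raise ValueError(f"y must be binary 0/1, found values {yvals}")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        y = y.astype(float)
        means = X.mean(axis=0)
        scales = X.std(axis=0)  # population convention
        constant = scales <= 0.0
        if constant.any():
            logger.info("flagged %d constant predictor column(s)", constant.sum())
        scales = np.where(constant, 1.0, scales)
        return cls(
            X=X,
            y=y,
            column_means=means,
            column_scales=scales,
            constant_mask=constant,
        )

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    def standardized(self) -> np.ndarray:
        if self._X_std is None:
            self._X_std = (self.X - self.column_means) / self.column_scales
        return self._X_std

    def subset(self, idx) -> "DesignData":
        """New DesignData from a row subset (re-standardized on the subset)."""
        return DesignData.from_arrays(self.X[idx], self.y[idx].astype(int))


@dataclass(frozen=True)
class FitControl:
    """Numerical controls for the EM coordinate-descent fit."""

    em_tol: float = 1e-4
    em_max_iter: int = 200
    cd_tol: float = 1e-6
    cd_max_iter: int = 500
    irls_max_iter: int = 50
    w_floor: float = 1e-5
    psi_bound: float = PSI_BOUND
    iar_tol: float = 1e-8
    iar_max_iter: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.em_tol, self.cd_tol, self.iar_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if min(self.em_max_iter, self.cd_max_iter, self.iar_max_iter) < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class FitResult:
    """Fitted model: coefficients on the original predictor scale plus
    inclusion diagnostics (None for traditional lasso/EN fits)."""

    intercept: float
    beta: np.ndarray
    beta_std: np.ndarray
    p: np.ndarray | None
    theta: np.ndarray | None
    psi: np.ndarray | None
    n_iter: int
    converged: bool
    objective_trace: np.ndarray
    prior: PriorSpec

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "intercept": float(self.intercept),
            "beta": arr(self.beta),
            "p": arr(self.p),
            "theta": arr(self.theta),
            "psi": arr(self.psi),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "objective_trace": arr(self.objective_trace),
            "prior": self.prior.to_dict(),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def cd_logistic(
    data: DesignData,
    penalty_nu: np.ndarray,
    xi: float,
    control: FitControl | None = None,
    warm_start: tuple[float, np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Penalized logistic coordinate descent on the standardized design.

    Maximizes ``l(b0, beta) - sum_j nu_j [xi |beta_j| + ((1-xi)/2) beta_j^2]``
    and returns ``(intercept, beta)`` on the standardized scale.
    """
    control = control or FitControl()
    Xs = np.ascontiguousarray(data.standardized().T)  # (J, N)
    nu = np.broadcast_to(np.asarray(penalty_nu, dtype=float), (data.n_predictors,))
    if np.any(nu < 0):
        raise ValueError("penalty_nu must be elementwise non-negative")
    if warm_start is None:
        b0, beta = 0.0, np.zeros(data.n_predictors)
    else:
        b0, beta = float(warm_start[0]), np.array(warm_start[1], dtype=float)
    b0, n_sweeps, status = _cd.irls_cd(
        Xs,
        data.y,
        np.ascontiguousarray(nu),
        float(xi),
        b0,
        beta,
        control.cd_tol,
        control.cd_max_iter,
        control.irls_max_iter,
        control.w_floor,
    )
    if status == _cd.NONFINITE:
        raise FloatingPointError("non-finite working responses in IRLS")
    if status == _cd.NOT_CONVERGED:
        warnings.warn(
            f"coordinate descent stopped after {n_sweeps} sweeps without "
            f"reaching tol={control.cd_tol}; returning best iterate",
            ConvergenceWarning,
        )
    return b0, beta


def _log_likelihood(b0: float, beta_std: np.ndarray, Xs: np.ndarray, y: np.ndarray):
    eta = b0 + Xs @ beta_std
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _penalized_objective_traditional(b0, beta_std, Xs, y, nu, xi):
    pen = float(np.sum(nu * (xi * np.abs(beta_std) + 0.5 * (1 - xi) * beta_std**2)))
    return _log_likelihood(b0, beta_std, Xs, y) - pen


def _marginal_objective(b0, beta_std, theta, psi, Xs, y, prior, L):
    """Penalized log posterior with the inclusion indicators marginalized."""
    log_slab = np.log(theta) + en_log_density(
        beta_std, prior.s1, prior.xi, prior.density_form
    )
    log_spike = np.log1p(-theta) + en_log_density(
        beta_std, prior.s0, prior.xi, prior.density_form
    )
    obj = _log_likelihood(b0, beta_std, Xs, y) + float(
        np.sum(np.logaddexp(log_slab, log_spike))
    )
    if L is not None:
        obj -= 0.5 * prior.tau**2 * float(psi @ (L @ psi))
    return obj


def fit_ssen(
    data: DesignData,
    prior: PriorSpec,
    graph: AdjacencyGraph | None = None,
    control: FitControl | None = None,
) -> FitResult:
    """Fit one of the six model variants selected by ``prior``.

    For ``prior.spike_slab=False`` this is a single penalized run with scale
    ``s0 (= s1)``; otherwise the EM loop alternates E-step, coordinate-descent
    M-step for the coefficients, and the theta update (IAR when
    ``prior.spatial``, shared mean of p otherwise).
    """
    control = control or FitControl()
    y = data.y
    if len(np.unique(y)) < 2:
        raise ValueError("y contains a single class; cannot fit a classifier")
    J = data.n_predictors
    if prior.spatial:
        if graph is None:
            raise ValueError("spatial prior requires an adjacency graph")
        if graph.n_nodes != J:
            raise ValueError(
                f"graph has {graph.n_nodes} nodes but the design has {J} predictors"
            )
    Xs = data.standardized()

    if not prior.spike_slab:
        nu = np.full(J, 1.0 / prior.s0)
        b0, beta_std = cd_logistic(data, nu, prior.xi, control)
        obj = _penalized_objective_traditional(b0, beta_std, Xs, y, nu, prior.xi)
        return _package_result(
            data, prior, b0, beta_std, None, None, None, 1, True, np.array([obj])
        )

    L = graph.laplacian().tocsr() if prior.spatial else None
    theta = np.full(J, 0.5)
    psi = np.zeros(J)
    b0, beta_std = 0.0, np.zeros(J)
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, control.em_max_iter + 1):
        p = e_step_inclusion(beta_std, theta, prior)
        nu = effective_inverse_scale(p, prior)
        beta_old = beta_std.copy()
        b0, beta_std = cd_logistic(
            data, nu, prior.xi, control, warm_start=(b0, beta_std)
        )
        if prior.spatial:
            fld: InclusionField = iar_update(
                p,
                graph,
                tau=prior.tau,
                psi_init=psi,
                bound=control.psi_bound,
                tol=control.iar_tol,
                max_iter=control.iar_max_iter,
            )
            theta, psi = fld.theta, fld.psi
        else:
            active = ~data.constant_mask
            tbar = float(np.clip(p[active].mean(), _THETA_EPS, 1 - _THETA_EPS))
            theta = np.full(J, tbar)
            psi = np.full(J, logit(tbar))
        trace.append(_marginal_objective(b0, beta_std, theta, psi, Xs, y, prior, L))
        if float(np.max(np.abs(beta_std - beta_old), initial=0.0)) < control.em_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM stopped at em_max_iter={control.em_max_iter} without meeting "
            f"tol={control.em_tol}",
            ConvergenceWarning,
        )
    p = e_step_inclusion(beta_std, theta, prior)
    return _package_result(
        data, prior, b0, beta_std, p, theta, psi, n_iter, converged, np.asarray(trace)
    )


def _package_result(data, prior, b0, beta_std, p, theta, psi, n_iter, converged, trace):
    beta = beta_std / data.column_scales
    beta[data.constant_mask] = 0.0
    intercept = float(b0 - np.sum(beta * data.column_means))
    return FitResult(
        intercept=intercept,
        beta=beta,
        beta_std=beta_std,
        p=p,
        theta=theta,
        psi=psi,
        n_iter=n_iter,
        converged=converged,
        objective_trace=trace,
        prior=prior,
    )


def predict_prob(fit: FitResult, X_new: np.ndarray) -> np.ndarray:
    """Predicted event probabilities expit(b0 + X beta) on the original scale."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != fit.beta.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, expected {fit.beta.shape[0]}"
        )
    return expit(fit.intercept + X_new @ fit.beta)
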