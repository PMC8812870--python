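"""Spatial neighbor structures and the IAR update of inclusion probabilities.

The intrinsic autoregressive (IAR) prior places an improper Gaussian Markov
random field on the logit prior inclusion probabilities psi_j = logit(theta_j),
penalizing squared differences of psi over the edges of a user-supplied
adjacency graph.  During EM fitting the M-step for the psi block maximizes

    Q(psi) = sum_j [ p_j psi_j - log(1 + exp(psi_j)) ]
             - (tau^2 / 2) * sum_{(i,j) in edges} (psi_j - psi_i)^2

where p_j are the current posterior inclusion probabilities.  Q is strictly
concave (after clipping) and is solved here by damped Newton iterations on the
graph Laplacian.  Each unordered edge contributes once to the penalty; a
double-counting convention would only rescale tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

#: Default bound on |psi_j|; keeps theta_j inside (~3.4e-4, 1 - 3.4e-4) so the
#: Bernoulli likelihood term never degenerates even when p_j is exactly 0 or 1.
PSI_BOUND = 8.0


class IARConvergenceError(RuntimeError):
    """Newton solver failed to converge; carries the last iterate in ``psi``."""

    def __init__(self, message: str, psi: np.ndarray):
        super().__init__(message)
        self.psi = psi


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected graph over predictor locations.

    Parameters
    ----------
    n_nodes:
        Number of predictors/locations.
    edges:
        ``(E, 2)`` integer array of unordered node pairs, each stored once
        with ``edges[:, 0] < edges[:, 1]``.
    """

    n_nodes: int
    edges: np.ndarray

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError(f"n_nodes must be positive, got {self.n_nodes}")
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.size:
            if e.min() < 0 or e.max() >= self.n_nodes:
                raise ValueError("edge indices out of range [0, n_nodes)")
            if np.any(e[:, 0] == e[:, 1]):
                raise ValueError("self-loops are not allowed")
            e = np.sort(e, axis=1)
            e = np.unique(e, axis=0)
        object.__setattr__(self, "edges", e)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def laplacian(self) -> sp.csr_matrix:
        """Combinatorial graph Laplacian L = D - A (rows sum to zero)."""
        n = self.n_nodes
        if not self.n_edges:
            return sp.csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate(
            [-np.ones(2 * self.n_edges), np.ones(2 * self.n_edges)]
        )
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    @classmethod
    def from_edge_list(cls, path, n_nodes: int | None = None) -> "AdjacencyGraph":
        """Read a two-column edge list (whitespace or comma delimited).

        Lines that do not parse as a pair of integers (e.g. a header) are
        skipped.  ``n_nodes`` defaults to ``max index + 1``.
        """
        pairs = []
        with open(path) as fh:
            for line in fh:
                parts = line.replace(",", " ").split()
                if len(parts) < 2:
                    continue
                try:
                    pairs.append((int(parts[0]), int(parts[1])))
                except ValueError:
                    continue  # header or comment line
        edges = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        if n_nodes is None:
            n_nodes = int(edges.max()) + 1 if edges.size else 1
        return cls(n_nodes=n_nodes, edges=edges)


def lattice_adjacency(n_rows: int, n_cols: int, scheme: str = "rook") -> AdjacencyGraph:
    """Adjacency graph of a 2-D lattice in row-major node order.

    ``rook`` connects horizontal/vertical neighbors; ``queen`` additionally
    connects diagonals.  Node index of lattice site (r, c) is ``r * n_cols + c``,
    matching the row-major vectorization used by the simulation generator.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"lattice dimensions must be positive, got {n_rows}x{n_cols}")
    if scheme not in ("rook", "queen"):
        raise ValueError(f"scheme must be 'rook' or 'queen', got {scheme!r}")
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    pairs = []
    # horizontal and vertical neighbors
    pairs.append(np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1))
    pairs.append(np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1))
    if scheme == "queen":
        pairs.append(np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()], axis=1))
        pairs.append(np.stack([idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()], axis=1))
    edges = np.concatenate(pairs, axis=0)
    return AdjacencyGraph(n_nodes=n_rows * n_cols, edges=edges)


@dataclass
class InclusionField:
    """Prior inclusion probabilities theta_j with their logits psi_j."""

    theta: np.ndarray
    psi: np.ndarray
    tau: float = 1.0
    n_iter: int = 0
    grad_norm: float = field(default=0.0)


def _objective(psi, p, L, tau):
    return float(
        np.sum(p * psi - np.logaddexp(0.0, psi)) - 0.5 * tau**2 * (psi @ (L @ psi))
    )


def iar_update(
    p: np.ndarray,
    graph: AdjacencyGraph,
    tau: float = 1.0,
    psi_init: np.ndarray | None = None,
    bound: float = PSI_BOUND,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> InclusionField:
    """Spatially smoothed M-step update of the inclusion field.

    Maximizes Q(psi) described in the module docstring given posterior
    inclusion probabilities ``p``; psi is clipped to ``[-bound, bound]``.
    Convergence is declared on the max-norm of the projected gradient
    (components pinned at the clip bound by an outward gradient are ignored).

    Returns
    -------
    InclusionField with ``theta = expit(psi)`` at the maximizer.

    Raises
    ------
    IARConvergenceError
        If the projected gradient norm does not fall below ``tol`` within
        ``max_iter`` Newton iterations; the exception carries the last iterate.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (graph.n_nodes,):
        raise ValueError(
            f"p has length {p.shape}, expected ({graph.n_nodes},) to match graph"
        )
    if tau <= 0:
        raise ValueError("tau must be positive")

    if graph.n_edges == 0:
        # no coupling: per-node Bernoulli maximizer is psi = logit(p), clipped
        with np.errstate(divide="ignore"):
            psi = np.clip(logit(np.clip(p, 0.0, 1.0)), -bound, bound)
        theta = expit(psi)
        return InclusionField(theta=theta, psi=psi, tau=tau, n_iter=0)

    L = graph.laplacian().tocsc()
    psi = (
        np.zeros(graph.n_nodes)
        if psi_init is None
        else np.clip(np.asarray(psi_init, dtype=float), -bound, bound)
    )
    q_old = _objective(psi, p, L, tau)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = expit(psi)
        grad = p - mu - tau**2 * (L @ psi)
        # coordinates pinned at the clip bound by an outward gradient are
        # frozen; the Newton system is solved on the free set only so pinned
        # coordinates cannot pollute the step direction
        pinned = ((psi >= bound) & (grad > 0)) | ((psi <= -bound) & (grad < 0))
        free = np.flatnonzero(~pinned)
        gnorm = float(np.max(np.abs(grad[free]))) if free.size else 0.0
        if gnorm < tol:
            theta = expit(psi)
            return InclusionField(
                theta=theta, psi=psi, tau=tau, n_iter=n_iter - 1, grad_norm=gnorm
            )
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = (sp.diags(w) + tau**2 * L).tocsr()[free][:, free].tocsc()
        step = np.zeros_like(psi)
        step[free] = splu(H).solve(grad[free])
        # damped step: halve until the concave objective does not decrease
        t = 1.0
        for _ in range(60):
            cand = np.clip(psi + t * step, -bound, bound)
            q_new = _objective(cand, p, L, tau)
            if q_new >= q_old - 1e-12:
                break
            t *= 0.5
        psi = cand
        q_old = q_new
    raise IARConvergenceError(
        f"IAR Newton did not converge in {max_iter} iterations "
        f"(projected gradient max-norm {gnorm:.3e})",
        psi,
    )
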