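"""Synthetic 2-D lattice predictor images with binary outcomes.

Each simulated dataset consists of N subject "images" on an n_rows x n_cols
lattice, drawn from a multivariate normal with a constant mean at every
location, unit variance, and correlation 0.9^d between locations at Euclidean
distance d.  The true coefficient map is zero except on a closed Euclidean
disc (default radius 4, which contains exactly 49 integer lattice points)
where it takes a single positive value.  Outcomes are Bernoulli with
logit-linear mean in the vectorized image, with no intercept.

The two standard study conditions are ``large_effect`` (signal 0.10 on a
40x40 lattice with predictor mean -1, N = 250) and ``small_effect`` (signal
0.05, mean -1.25); both yield event rates around 13-14%.  Images are
vectorized row-major, matching the node ordering of ``lattice_adjacency``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.special import expit


@dataclass(frozen=True)
class SimScenario:
    """Fully determines one simulated dataset given its seed."""

    n_rows: int = 40
    n_cols: int = 40
    n_subjects: int = 250
    signal_value: float = 0.10
    signal_center: tuple[int, int] | None = None  # defaults to lattice center
    signal_radius: float = 4.0
    predictor_mean: float = -1.0
    rho: float = 0.90
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        if self.signal_radius < 0:
            raise ValueError("signal_radius must be non-negative")

    @property
    def center(self) -> tuple[int, int]:
        if self.signal_center is not None:
            return self.signal_center
        return (self.n_rows // 2, self.n_cols // 2)

    @property
    def n_locations(self) -> int:
        return self.n_rows * self.n_cols

    def to_dict(self) -> dict:
        d = asdict(self)
        d["signal_center"] = list(self.center)
        return d


def large_effect(seed: int = 0, **kw) -> SimScenario:
    """Large-effect condition: signal 0.10, predictor mean -1."""
    return SimScenario(signal_value=0.10, predictor_mean=-1.0, seed=seed, **kw)


def small_effect(seed: int = 0, **kw) -> SimScenario:
    """Small-effect condition: signal 0.05, predictor mean -1.25."""
    return SimScenario(signal_value=0.05, predictor_mean=-1.25, seed=seed, **kw)


@dataclass
class SimDataset:
    X: np.ndarray  # N x (n_rows * n_cols), row-major vectorized images
    y: np.ndarray
    beta_true: np.ndarray
    scenario: SimScenario

    def to_csv(self, path):
        """Write features x0001..xJ plus the label column y."""
        j = self.X.shape[1]
        cols = [f"x{i + 1:04d}" for i in range(j)]
        df = pd.DataFrame(self.X, columns=cols)
        df["y"] = self.y.astype(int)
        df.to_csv(path, index=False)


def build_beta_image(scenario: SimScenario) -> np.ndarray:
    """True coefficient vector: signal on the closed disc, zero elsewhere."""
    r0, c0 = scenario.center
    rad = scenario.signal_radius
    if (
        r0 - rad < 0
        or c0 - rad < 0
        or r0 + rad > scenario.n_rows - 1
        or c0 + rad > scenario.n_cols - 1
    ):
        raise ValueError("signal disc exceeds the lattice bounds")
    rr, cc = np.meshgrid(
        np.arange(scenario.n_rows), np.arange(scenario.n_cols), indexing="ij"
    )
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    beta = np.where(mask, scenario.signal_value, 0.0)
    return beta.ravel()  # row-major


def lattice_coordinates(n_rows: int, n_cols: int) -> np.ndarray:
    """(J, 2) array of (row, col) coordinates in row-major node order."""
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)


@lru_cache(maxsize=4)
def _correlation_cholesky(n_rows: int, n_cols: int, rho: float) -> np.ndarray:
    """Upper Cholesky factor of the 0.9^d correlation matrix (cached)."""
    coords = lattice_coordinates(n_rows, n_cols)
    d = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    )
    sigma = rho**d
    return cholesky(sigma, lower=False)  # sigma = U.T @ U


def simulate_predictors(
    scenario: SimScenario, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n independent MVN(mean * 1, Sigma) draws, Sigma_jk = rho^d(j,k)."""
    U = _correlation_cholesky(scenario.n_rows, scenario.n_cols, scenario.rho)
    z = rng.standard_normal((n, scenario.n_locations))
    return scenario.predictor_mean + z @ U


def simulate_outcomes(
    X: np.ndarray, beta_true: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli outcomes with mean expit(X beta); no intercept term."""
    X = np.asarray(X, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    if X.shape[1] != beta_true.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns but beta_true has {beta_true.shape[0]}"
        )
    p = expit(X @ beta_true)
    return rng.binomial(1, p)


def generate_dataset(scenario: SimScenario) -> SimDataset:
    """Compose coefficient map, predictors, and outcomes; reproducible from
    ``scenario.seed`` via independent substreams for X and y."""
    beta = build_beta_image(scenario)
    ss = np.random.SeedSequence(scenario.seed)
    rng_x, rng_y = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(2))
    X = simulate_predictors(scenario, scenario.n_subjects, rng_x)
    y = simulate_outcomes(X, beta, rng_y)
    return SimDataset(X=X, y=y, beta_true=beta, scenario=scenario)


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds (each below 2^31)."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def image_to_vector(img: np.ndarray) -> np.ndarray:
    return np.asarray(img).ravel()


def vector_to_image(vec: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    return np.asarray(vec).reshape(n_rows, n_cols)


def write_manifest(scenario: SimScenario, path):
    with open(path, "w") as fh:
        json.dump(scenario.to_dict(), fh, indent=2)
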