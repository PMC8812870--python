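"""Spike-and-slab elastic net prior: mixture density, E-step, effective penalties.

The prior on each coefficient beta_j is a two-point scale mixture

    beta_j | gamma_j  ~  EN(beta_j | 0, S_j),   S_j = (1 - gamma_j) s0 + gamma_j s1,

where gamma_j in {0, 1} indicates slab membership, s1 > s0 > 0, and EN is an
elastic-net mixture of a Gaussian-type and a double-exponential-type component
weighted by ``1 - xi`` and ``xi``.  With ``xi = 1`` this is the spike-and-slab
lasso, with ``xi = 0`` a spike-and-slab ridge, and ``xi = 0.5`` the
spike-and-slab elastic net.

Two functional forms of the EN density are supported:

* ``printed`` (default): components ``exp(-log(2 pi S) - beta^2 / S)`` and
  ``exp(-log(2 S) - |beta| / S)``.  The Gaussian-type component is not a
  normalized Gaussian; since the E-step uses only ratios of the same
  functional form the choice is internally consistent.
* ``normalized``: a proper Normal(0, S) density for the quadratic component,
  ``exp(-0.5 log(2 pi S) - beta^2 / (2 S))``.

The E-step computes the posterior slab probability p_j and the effective
inverse scale nu_j = E[1/S_j] = p_j/s1 + (1 - p_j)/s0, which multiplies the
per-coefficient elastic-net penalty in the coordinate-descent M-step.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

_MODEL_TABLE = {
    # name: (xi, spike_slab, spatial)
    "lasso": (1.0, False, False),
    "en": (0.5, False, False),
    "ssl": (1.0, True, False),
    "ssen": (0.5, True, False),
    "ssl-iar": (1.0, True, True),
    "ssen-iar": (0.5, True, True),
}

MODEL_NAMES = tuple(_MODEL_TABLE)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters and structural flags selecting one of the six models.

    Parameters
    ----------
    xi:
        Elastic-net mixture weight in [0, 1]; 1 = lasso-type, 0 = ridge-type.
    s0, s1:
        Spike and slab scales, ``0 < s0 <= s1``.  For traditional (non
        spike-and-slab) fits ``s0 == s1`` is the single penalty scale lambda.
    spike_slab:
        If False the fit is a single penalized run with scale s0 (= s1).
    spatial:
        If True the prior inclusion probabilities are smoothed by the IAR
        update over an adjacency graph.
    tau:
        IAR precision scale (conventionally fixed at 1).
    density_form:
        ``printed`` or ``normalized`` (see module docstring).
    """

    xi: float
    s0: float
    s1: float
    spike_slab: bool = True
    spatial: bool = False
    tau: float = 1.0
    density_form: str = "printed"

    def __post_init__(self):
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError(f"xi must be in [0, 1], got {self.xi}")
        if not 0.0 < self.s0 <= self.s1:
            raise ValueError(f"require 0 < s0 <= s1, got s0={self.s0}, s1={self.s1}")
        if not self.spike_slab and self.s0 != self.s1:
            raise ValueError("spike_slab=False requires s0 == s1 (single penalty)")
        if self.spatial and not self.spike_slab:
            raise ValueError("spatial smoothing requires spike_slab=True")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.density_form not in ("printed", "normalized"):
            raise ValueError(f"unknown density_form {self.density_form!r}")

    @classmethod
    def from_model_name(
        cls, name: str, s0: float, s1: float | None = None, tau: float = 1.0
    ) -> "PriorSpec":
        """Build the PriorSpec for a named model variant.

        ``lasso``/``en`` ignore ``s1`` (single scale ``s0``); spike-and-slab
        variants require both scales.
        """
        key = name.lower()
        if key not in _MODEL_TABLE:
            raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
        xi, spike_slab, spatial = _MODEL_TABLE[key]
        if not spike_slab:
            s1 = s0
        elif s1 is None:
            raise ValueError(f"model {name!r} requires a slab scale s1")
        return cls(xi=xi, s0=s0, s1=s1, spike_slab=spike_slab, spatial=spatial, tau=tau)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)


def en_log_density(beta, S, xi: float, form: str = "printed"):
    """Log of the elastic-net mixture density EN(beta | 0, S).

    Vectorized over ``beta``; evaluated in log space via logaddexp so that
    extreme arguments and xi in {0, 1} are handled exactly.
    """
    beta = np.asarray(beta, dtype=float)
    S = float(S)
    if S <= 0:
        raise ValueError(f"scale S must be positive, got {S}")
    if form == "printed":
        log_gauss = -np.log(2.0 * np.pi * S) - beta**2 / S
    elif form == "normalized":
        log_gauss = -0.5 * np.log(2.0 * np.pi * S) - beta**2 / (2.0 * S)
    else:
        raise ValueError(f"unknown density form {form!r}")
    log_de = -np.log(2.0 * S) - np.abs(beta) / S
    with np.errstate(divide="ignore"):
        a = np.log1p(-xi) + log_gauss if xi < 1.0 else np.full_like(log_gauss, -np.inf)
        b = np.log(xi) + log_de if xi > 0.0 else np.full_like(log_de, -np.inf)
    return np.logaddexp(a, b)


def e_step_inclusion(beta, theta, prior: PriorSpec):
    """Posterior slab-inclusion probabilities p_j = E[gamma_j | beta_j, theta_j].

    p_j = theta_j EN(beta_j|0,s1) / [theta_j EN(beta_j|0,s1)
                                     + (1-theta_j) EN(beta_j|0,s0)],
    computed in log space.  ``beta`` and ``theta`` broadcast elementwise.
    """
    beta = np.asarray(beta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0.0) or np.any(theta >= 1.0):
        raise ValueError("theta must lie strictly inside (0, 1)")
    log_slab = np.log(theta) + en_log_density(beta, prior.s1, prior.xi, prior.density_form)
    log_spike = np.log1p(-theta) + en_log_density(
        beta, prior.s0, prior.xi, prior.density_form
    )
    # p = 1 / (1 + exp(log_spike - log_slab)), stable in both tails
    return np.exp(log_slab - np.logaddexp(log_slab, log_spike))


def effective_inverse_scale(p, prior: PriorSpec):
    """Expected inverse scale nu_j = p_j / s1 + (1 - p_j) / s0.

    Multiplies the elastic-net penalty of coefficient j in the M-step; lies in
    [1/s1, 1/s0], decreasing in p_j (more inclusion, weaker penalty).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("inclusion probabilities must lie in [0, 1]")
    return p / prior.s1 + (1.0 - p) / prior.s0
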