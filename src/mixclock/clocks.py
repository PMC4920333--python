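"""Relaxed clock models: Brownian, gamma white noise, and their mixture.

Three rate processes over a dated tree:

* **Brownian (lognormal) clock** — the log instantaneous rate ``x(t)``
  evolves as Brownian motion with variance ``sigma2_b`` per Myr; the tree
  stores one ``x`` value per node and the branch rate is approximated by the
  arithmetic average of the endpoint rates,
  ``r_j = (exp(x_up) + exp(x_dn)) / 2``.
* **White-noise clock** — branch-averaged rate multipliers ``R_j`` are
  independent gamma variables with mean ``mu_W`` and variance
  ``sigma2_W / dt_j``, shrinking with branch duration: the continuous-time
  uncorrelated clock.
* **Mixed clock** — log rates add (equivalently branch rates multiply):
  ``l_j = dt_j * r_j^BM * R_j`` with ``mu_W`` pinned to 1 for
  identifiability.

The across-branch variance of log branch rates splits additively into the
two components; the white-noise fraction ``f_W = v_W / (v_B + v_W)`` is the
variance-partition statistic reported per MCMC draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .timetree import TimeTree

__all__ = [
    "BrownianState", "WhiteNoiseState", "MixedState", "VariancePartition",
    "SIGMA_B_RANGE", "X0_RANGE",
    "bm_logprior", "bm_branch_rates", "wn_logprior", "wn_gamma_shape_rate",
    "effective_lengths", "variance_partition",
]

#: truncation of the Jeffreys prior on sigma_b (so sigma2_b in [1e-6, 1e6])
SIGMA_B_RANGE = (1e-3, 1e3)
#: truncated-uniform prior range for the root log-rate x(0)
X0_RANGE = (-100.0, 100.0)


@dataclass
class BrownianState:
    """Node log-rates and Brownian variance per Myr."""

    x: np.ndarray          # (2P-1,) log instantaneous rate at every node
    sigma2_b: float        # Brownian variance per Myr

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)

    @property
    def x0(self) -> float:
        """Root log-rate (node 0)."""
        return float(self.x[0])


@dataclass
class WhiteNoiseState:
    """Per-branch gamma multipliers and stationary moments."""

    R: np.ndarray          # (2P-1,) multipliers, entry 0 (root) unused/1
    mu_w: float = 1.0      # stationary mean (fixed to 1 in mixed mode)
    sigma2_w: float = 1.0  # stationary variance

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        if np.any(self.R[1:] <= 0):
            raise ValueError("white-noise multipliers must be positive")


@dataclass
class MixedState:
    bm: BrownianState
    wn: WhiteNoiseState

    def __post_init__(self):
        if self.wn.mu_w != 1.0:
            raise ValueError("the mixed clock pins the white-noise mean to 1")


@dataclass
class VariancePartition:
    v_b: float
    v_w: float

    @property
    def f_w(self) -> float | None:
        tot = self.v_b + self.v_w
        if tot == 0:
            return None
        return self.v_w / tot


def _jeffreys_sigma2_logprior(sigma2: float) -> float:
    """Jeffreys prior on sigma_b, truncated, expressed on sigma2 = sigma_b**2."""
    lo, hi = SIGMA_B_RANGE
    if not lo * lo <= sigma2 <= hi * hi:
        return -np.inf
    # p(sigma) ~ 1/sigma  =>  p(sigma2) ~ 1/sigma2 (up to truncation constant)
    return -np.log(sigma2) - np.log(2.0 * np.log(hi / lo))


def bm_logprior(state: BrownianState, tree: TimeTree,
                include_hyper: bool = True) -> float:
    """Log-density of the node log-rate configuration under the Brownian clock.

    By the Markov property this is a product of independent normal
    increments ``x_child ~ N(x_parent, sigma2_b * dt)`` over the 2P-2
    branches, plus (optionally) the truncated Jeffreys prior on sigma_b and
    the truncated uniform prior on the root log-rate.
    """
    dt = tree.durations()
    if np.any(dt <= 0):
        raise ValueError("non-positive branch duration")
    lp = 0.0
    if include_hyper:
        lp += _jeffreys_sigma2_logprior(state.sigma2_b)
        lo, hi = X0_RANGE
        if not lo <= state.x0 <= hi:
            return -np.inf
        lp -= np.log(hi - lo)
        if not np.isfinite(lp):
            return -np.inf
    var = state.sigma2_b * dt
    diff = state.x[1:] - state.x[tree.parent[1:]]
    lp += float(np.sum(-0.5 * np.log(2.0 * np.pi * var) - diff**2 / (2.0 * var)))
    return lp


def bm_branch_rates(state: BrownianState, tree: TimeTree) -> np.ndarray:
    """Arithmetic endpoint-average branch rates, indexed by child node.

    Entry 0 (the root) is set to 0 and never used.
    """
    er = np.exp(state.x)
    r = np.zeros(tree.n_nodes)
    r[1:] = 0.5 * (er[tree.parent[1:]] + er[1:])
    return r


def wn_gamma_shape_rate(mu_w: float, sigma2_w: float, dt: np.ndarray):
    """Gamma (shape, rate) giving mean mu_W and variance sigma2_W / dt."""
    alpha = mu_w * mu_w * dt / sigma2_w
    beta = mu_w * dt / sigma2_w
    return alpha, beta


def wn_logprior(state: WhiteNoiseState, tree: TimeTree,
                include_hyper: bool = True, mixed: bool = False) -> float:
    """Log-density of branch multipliers under the white-noise clock.

    Each ``R_j`` is gamma with mean ``mu_W`` and variance ``sigma2_W/dt_j``.
    Hyperpriors are exponential with mean 1 on both stationary moments; the
    mean term is omitted in mixed mode where ``mu_W == 1``.
    """
    if state.sigma2_w <= 0 or state.mu_w <= 0:
        return -np.inf
    dt = tree.durations()
    alpha, beta = wn_gamma_shape_rate(state.mu_w, state.sigma2_w, dt)
    lp = float(np.sum(_gamma_dist.logpdf(state.R[1:], alpha, scale=1.0 / beta)))
    if include_hyper:
        lp += -state.sigma2_w  # Exp(1), log density up to 0 constant
        if not mixed:
            lp += -state.mu_w
    return lp


def effective_lengths(clock_state, tree: TimeTree) -> np.ndarray:
    """Expected substitutions per site on each branch (entry 0 unused).

    * Brownian: ``dt_j * r_j^BM``
    * white noise: ``dt_j * R_j``
    * mixed: ``dt_j * r_j^BM * R_j``
    """
    ell = np.zeros(tree.n_nodes)
    dt = tree.durations()
    if isinstance(clock_state, BrownianState):
        ell[1:] = dt * bm_branch_rates(clock_state, tree)[1:]
    elif isinstance(clock_state, WhiteNoiseState):
        ell[1:] = dt * clock_state.R[1:]
    elif isinstance(clock_state, MixedState):
        ell[1:] = dt * bm_branch_rates(clock_state.bm, tree)[1:] * clock_state.wn.R[1:]
    else:
        raise TypeError(f"unknown clock state {type(clock_state).__name__}")
    return ell


def variance_partition(state: MixedState, tree: TimeTree) -> VariancePartition:
    """Partition of across-branch log-rate variance between the components.

    Unweighted sample variances over the 2P-2 branches of the log Brownian
    branch rates and the log white-noise multipliers.
    """
    if tree.n_branches < 2:
        raise ValueError("variance partition needs at least two branches")
    # log branch rates computed directly on the log scale for stability
    x = state.bm.x
    log_rb = np.logaddexp(x[tree.parent[1:]], x[1:]) - np.log(2.0)
    log_rw = np.log(state.wn.R[1:])
    return VariancePartition(float(np.var(log_rb, ddof=1)),
                             float(np.var(log_rw, ddof=1)))
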