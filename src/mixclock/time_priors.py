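"""Priors on divergence times.

Node dating uses the reconstructed birth-death prior with incomplete species
sampling, conditioned on the root age and the tip count.  Only two
combinations of (birth rate lambda, death rate mu, sampling fraction rho)
are identifiable on a reconstructed extant tree; they are parametrized here
as the net diversification ``d = lambda - mu`` and the sampling-scaled birth
``b = lambda * rho``.  Conditional on the root age, the P-2 non-root node
ages are i.i.d. with normalized density ``nu(t) = p1(t) / int_0^troot p1``,
where ``p1(t) = b d^2 e^{-dt} / (b + (d-b) e^{-dt})^2``.  Hard calibration
bounds truncate this density without renormalization (only density ratios
enter the MCMC).

Tip dating uses a serially sampled birth-death process: constant speciation
``lambda``, extinction ``mu`` and fossil-sampling ``psi`` rates operate
between the root and a cut-off time ``t_c``; fossil sampling kills the
lineage, so every sampled fossil is a tip.  No event of any kind happens
after ``t_c``; each lineage alive at the cut-off is represented by exactly
one extant tip (diversified sampling), and the unobserved diversity behind
the cut-off enters through a pure-birth growth factor P(N_tot | n).  The
density conditions on the root age and on both root children leaving
sampled descendants, matching the forward simulator, and is built from the
standard survival machinery: with

    c1 = sqrt((lambda - mu - psi)^2 + 4 lambda psi)
    c2 = (lambda + mu + psi) / c1

``p0(z)`` is the probability that a lineage ``z`` Myr above the cut-off
leaves no sampled descendant, and ``q(z)`` the per-branch density factor
(q(0) = 1 at the cut-off, where extant sampling has probability 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .timetree import TimeTree

__all__ = [
    "NodeBDParams", "SerialBDParams", "log_p1", "cum_p1", "sample_node_ages",
    "node_bd_logdensity", "log_q", "p0", "serial_bd_logdensity",
    "check_tip_dating_shape", "ntot_logprob",
]


@dataclass
class NodeBDParams:
    """Identifiable reconstructed-BD pair: d = lambda - mu, b = lambda * rho."""

    d: float
    b: float

    def __post_init__(self):
        if self.d <= 0 or self.b <= 0:
            raise ValueError("d and b must be positive")


@dataclass
class SerialBDParams:
    """Serially sampled BD parameters (rates per Myr)."""

    d: float            # net diversification lambda - mu
    mu: float           # extinction rate
    psi: float          # fossil sampling rate
    t_c: float = 25.0   # cut-off time (Myr); no events younger than this
    n_tot: int = 5000   # total extant diversity represented by the cut-off lineages

    def __post_init__(self):
        if self.d <= 0 or self.mu < 0 or self.psi < 0:
            raise ValueError("need d > 0, mu >= 0, psi >= 0")
        if self.t_c <= 0:
            raise ValueError("cut-off time must be positive")

    @property
    def lam(self) -> float:
        return self.d + self.mu


# ----------------------------------------------------------------------
# node dating: reconstructed BD with species sampling
# ----------------------------------------------------------------------
def log_p1(t, d: float, b: float):
    """Log of the unnormalized node-age kernel p1(t)."""
    t = np.asarray(t, dtype=float)
    e = np.exp(-d * t)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log(b) + 2.0 * np.log(d) - d * t - 2.0 * np.log(b + (d - b) * e)
    return np.where(t < 0, -np.inf, out)


def cum_p1(t, d: float, b: float):
    """Closed-form integral of p1 over (0, t)."""
    t = np.asarray(t, dtype=float)
    B = d - b
    if abs(B) < 1e-10 * d:
        return 1.0 - np.exp(-d * t)  # Yule-like limit b -> d
    e = np.exp(-d * t)
    return (b * d / B) * (1.0 / (b + B * e) - 1.0 / d)


def sample_node_ages(n: int, t_root: float, d: float, b: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. node ages from nu(t) on (0, t_root) by CDF inversion."""
    U = rng.random(n) * cum_p1(t_root, d, b)
    B = d - b
    if abs(B) < 1e-10 * d:
        return -np.log1p(-U) / d
    inv = 1.0 / (U * B / (b * d) + 1.0 / d)
    u = (inv - b) / B
    return -np.log(u) / d


def node_bd_logdensity(tree: TimeTree, params: NodeBDParams,
                       bounds: dict | None = None, include_hyper: bool = False,
                       hyper_means=(1.0, 1.0)) -> float:
    """Log-density of the non-root node ages given the root age.

    The P-2 free ages are i.i.d. nu(t); hard calibration bounds contribute a
    truncation indicator (-inf on violation).  Requires an ultrametric
    extant tree.
    """
    if np.any(tree.fossil):
        raise ValueError("node-dating prior requires an extant (ultrametric) tree")
    internal = tree.internal
    free = internal[internal != 0]
    ages = tree.ages[free]
    troot = tree.root_age
    if bounds:
        for v, (lo, hi) in bounds.items():
            a = tree.ages[v]
            if (lo is not None and a < lo) or (hi is not None and a > hi):
                return -np.inf
    lp = float(np.sum(log_p1(ages, params.d, params.b))
               - free.size * np.log(cum_p1(troot, params.d, params.b)))
    if include_hyper:
        md, mb = hyper_means
        lp += -params.d / md - np.log(md) - params.b / mb - np.log(mb)
    return lp


# ----------------------------------------------------------------------
# tip dating: serially sampled BD with diversified sampling
# ----------------------------------------------------------------------
def _c1c2(lam: float, mu: float, psi: float):
    c1 = np.sqrt((lam - mu - psi) ** 2 + 4.0 * lam * psi)
    if c1 <= 0:
        raise ValueError("degenerate serial-BD parameters (c1 = 0)")
    return c1, (lam + mu + psi) / c1


def log_q(z, lam: float, mu: float, psi: float):
    """Log per-branch density factor at height z above the cut-off."""
    z = np.asarray(z, dtype=float)
    c1, c2 = _c1c2(lam, mu, psi)
    den = np.exp(-c1 * z) * (1.0 - c2) + (1.0 + c2)
    return np.log(4.0) - c1 * z - 2.0 * np.log(den)


def p0(z, lam: float, mu: float, psi: float):
    """P(no sampled descendants) for a lineage z Myr above the cut-off."""
    z = np.asarray(z, dtype=float)
    c1, c2 = _c1c2(lam, mu, psi)
    e = np.exp(-c1 * z)
    frac = (e * (1.0 - c2) - (1.0 + c2)) / (e * (1.0 - c2) + (1.0 + c2))
    return (lam + mu + psi + c1 * frac) / (2.0 * lam)


def ntot_logprob(n_tot: int, n_cutoff: int, lam: float, t_c: float) -> float:
    """log P(N_tot extant species | n cut-off lineages) under pure birth.

    Each of the n lineages crossing the cut-off grows for t_c Myr without
    extinction; clade sizes are i.i.d. geometric, so the total is shifted
    negative-binomial.
    """
    if n_tot < n_cutoff:
        return -np.inf
    logp = -lam * t_c
    log1mp = np.log(-np.expm1(-lam * t_c)) if lam * t_c > 0 else -np.inf
    out = (gammaln(n_tot) - gammaln(n_cutoff) - gammaln(n_tot - n_cutoff + 1)
           + n_cutoff * logp)
    if n_tot > n_cutoff:
        out += (n_tot - n_cutoff) * log1mp
    return float(out)


def check_tip_dating_shape(tree: TimeTree, t_c: float):
    """Verify the diversified-sampling topology constraint.

    Every lineage crossing the cut-off must subtend exactly one extant tip;
    equivalently no node younger than t_c may be ancestral to two or more
    extant tips.  Fossil tips never trigger the check.  Returns
    ``(ok, offending_nodes)``.
    """
    has_extant = np.zeros(tree.n_nodes, dtype=bool)
    for v in tree.postorder():
        if tree.is_tip[v]:
            has_extant[v] = not tree.fossil[v]
        else:
            has_extant[v] = (has_extant[tree.children[v, 0]]
                             or has_extant[tree.children[v, 1]])
    offending = []
    for v in tree.internal:
        if tree.ages[v] <= t_c and bool(has_extant[tree.children[v, 0]]
                                        and has_extant[tree.children[v, 1]]):
            offending.append(int(v))
    return (len(offending) == 0, offending)


def serial_bd_logdensity(tree: TimeTree, params: SerialBDParams,
                         fossil_intervals: dict | None = None,
                         include_ntot: bool = True,
                         n_tot_obs: int | None = None) -> float:
    """Log-density of a serially sampled tree, conditional on its root age.

    Telescoping the per-branch factors q(z_up)/q(z_dn) over the tree gives

        2 log q(z_root) - 2 log(1 - p0(z_root))
        + sum_{non-root internal i} [log lambda + log q(z_i)]
        + sum_{fossil tips j}       [log psi    - log q(z_j)]
        (+ log P(N_tot | n extant)  pure-birth diversity factor)

    with z = age - t_c.  Any event at or below the cut-off, a diversified-
    sampling shape violation, or a fossil outside its age interval gives
    -inf.
    """
    lam, mu, psi, t_c = params.lam, params.mu, params.psi, params.t_c
    ages = tree.ages
    internal = tree.internal
    fossils = np.flatnonzero(tree.fossil & tree.is_tip)
    if np.any(ages[internal] <= t_c) or np.any(ages[fossils] <= t_c):
        return -np.inf
    ok, _ = check_tip_dating_shape(tree, t_c)
    if not ok:
        return -np.inf
    if fossil_intervals:
        lab2node = tree.tip_label_to_node
        for lab, (lo, hi) in fossil_intervals.items():
            a = ages[lab2node[lab]]
            if not lo <= a <= hi:
                return -np.inf
    if fossils.size > 0 and psi <= 0:
        return -np.inf
    z_root = ages[0] - t_c
    free = internal[internal != 0]
    lp = 2.0 * float(log_q(z_root, lam, mu, psi))
    surv = 1.0 - float(p0(z_root, lam, mu, psi))
    if surv <= 0:
        return -np.inf
    lp -= 2.0 * np.log(surv)
    lp += free.size * np.log(lam) + float(np.sum(log_q(ages[free] - t_c,
                                                       lam, mu, psi)))
    if fossils.size:
        lp += fossils.size * np.log(psi) - float(np.sum(log_q(ages[fossils] - t_c,
                                                              lam, mu, psi)))
    if include_ntot:
        n_extant = int(np.sum(tree.is_tip & ~tree.fossil))
        n_tot = params.n_tot if n_tot_obs is None else n_tot_obs
        lp += ntot_logprob(n_tot, n_extant, lam, t_c)
    return float(lp)
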