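"""Stochastic mapping of substitution histories and sufficient statistics.

One Gibbs refresh of the sampler draws, for every site, an explicit
substitution history over the whole tree from its conditional posterior:
first internal node states by backward filtering / forward sampling, then an
endpoint-conditioned CTMC path on every branch by uniformization (jump
counts from the conditioned Poisson mixture, intermediate states from the
conditioned jump chain, jump times as uniform order statistics).

Only the per-branch sufficient statistics of those paths are kept: pairwise
substitution counts ``n_ab(j)`` and per-state dwell times ``w_a(j)``.  Dwell
is recorded in *relative* branch units, summing to the site count on every
branch, so the augmented log-likelihood is an explicit function of each
effective branch length and rate/time updates never touch the pruning
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .gtr import RateMatrix, _pruning_pass
from .io import Alignment
from .timetree import TimeTree

__all__ = ["SuffStats", "sample_mapping", "suffstat_loglik"]


@dataclass
class SuffStats:
    """Per-branch substitution counts and relative dwell times.

    ``counts[j, a, b]`` (a != b) is the number of a->b events on branch j
    summed over sites; ``dwell[j, a]`` is the time spent in state a in units
    of the branch duration, summed over sites (so ``dwell[j].sum() ==
    n_sites``).  Row/entry 0 (the root, which has no branch) is unused.
    """

    counts: np.ndarray  # (n_nodes, 4, 4)
    dwell: np.ndarray   # (n_nodes, 4)
    n_sites: int
    root_counts: np.ndarray = None  # (4,) sampled root states per nucleotide

    def __post_init__(self):
        if self.root_counts is None:
            self.root_counts = np.zeros(4)

    def events_per_branch(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def branch_terms(self, Q: RateMatrix):
        """Pieces of the augmented log-likelihood, per branch.

        Returns ``(n_tot, nlogq, wq)`` such that the branch-j term is
        ``n_tot[j] * log(l_j) + nlogq[j] + l_j * wq[j]``.
        """
        off = ~np.eye(4, dtype=bool)
        logQ = np.full((4, 4), -np.inf)
        pos = Q.Q > 0
        logQ[pos] = np.log(Q.Q[pos])
        n_tot = self.counts.sum(axis=(1, 2))
        with np.errstate(invalid="ignore"):
            nlogq = np.where(self.counts[:, off] > 0,
                             self.counts[:, off] * logQ[off][None, :], 0.0).sum(axis=1)
        wq = self.dwell @ np.diag(Q.Q)
        return n_tot, nlogq, wq


def suffstat_loglik(S: SuffStats, Q: RateMatrix, lengths) -> float:
    """Log-probability density of the augmented substitution histories.

    ``sum_a c_a log pi_a + sum_j [ sum_{a!=b} n_ab(j) log(l_j Q_ab) +
    l_j sum_a w_a(j) Q_aa ]`` where ``c_a`` counts the sampled root states
    (jump-time order statistics contribute no length-dependent factor in
    relative dwell units).  A branch with events but zero length is an
    impossible history (-inf).
    """
    lengths = np.asarray(lengths, dtype=float)
    n_tot, nlogq, wq = S.branch_terms(Q)
    lp = float(S.root_counts @ np.log(Q.pi))
    for j in range(1, lengths.shape[0]):
        if lengths[j] <= 0:
            if n_tot[j] > 0:
                return -np.inf
            continue
        lp += n_tot[j] * np.log(lengths[j]) + nlogq[j] + lengths[j] * wq[j]
    return float(lp)


def _sample_categorical(probs: np.ndarray, rng) -> np.ndarray:
    """Row-wise categorical draw from unnormalized (n, k) probabilities."""
    cum = probs.cumsum(axis=1)
    u = rng.random(probs.shape[0]) * cum[:, -1]
    return (cum < u[:, None]).sum(axis=1)


def sample_node_states(tree: TimeTree, lengths, aln: Alignment, Q: RateMatrix,
                       rng, tip_masks=None) -> np.ndarray:
    """Joint draw of all node states from their conditional posterior."""
    partial, _ = _pruning_pass(tree, lengths, aln, Q, tip_masks=tip_masks)
    P = Q.transition_probs(np.asarray(lengths, dtype=float))
    states = np.zeros((tree.n_nodes, aln.n_sites), dtype=np.int64)
    states[0] = _sample_categorical(partial[0] * Q.pi[None, :], rng)
    for v in range(1, tree.n_nodes):
        probs = P[v][states[tree.parent[v]]] * partial[v]
        states[v] = _sample_categorical(probs, rng)
    return states


def sample_mapping(tree: TimeTree, lengths, aln: Alignment, Q: RateMatrix,
                   rng: np.random.Generator, tip_masks=None) -> SuffStats:
    """Draw substitution histories for all sites and reduce to SuffStats."""
    lengths = np.asarray(lengths, dtype=float)
    states = sample_node_states(tree, lengths, aln, Q, rng, tip_masks=tip_masks)
    n_nodes, n_sites = tree.n_nodes, aln.n_sites
    root_counts = np.bincount(states[0], minlength=4).astype(float)
    B = n_nodes - 1

    omega = 1.05 * Q.omega
    R = np.eye(4) + Q.Q / omega

    counts = np.zeros((n_nodes, 4, 4))
    dwell = np.zeros((n_nodes, 4))

    a = states[tree.parent[1:]]      # (B, S) branch up-states
    b = states[1:]                   # (B, S) branch down-states
    m = omega * lengths[1:]          # (B,) uniformized intensities
    if np.any((m <= 0) & np.any(a != b, axis=1)):
        raise ValueError("zero-length branch with unequal endpoint states")

    max_m = float(m.max(initial=0.0))
    n_top = int(max_m + 8.0 * np.sqrt(max_m + 1.0) + 12.0)
    Rpow = np.empty((n_top + 1, 4, 4))
    Rpow[0] = np.eye(4)
    for n in range(1, n_top + 1):
        Rpow[n] = Rpow[n - 1] @ R

    # P(N = n | a, b) ~ Pois(n; m_j) R^n[a, b]; weights sum to P(l)[a, b]
    ns = np.arange(n_top + 1)
    with np.errstate(divide="ignore"):
        pois = np.exp(ns[:, None] * np.log(np.where(m > 0, m, 1.0))[None, :]
                      - m[None, :] - gammaln(ns + 1)[:, None])
    pois[1:, m <= 0] = 0.0
    cum = np.cumsum(pois[:, :, None] * Rpow.reshape(n_top + 1, 1, 16), axis=0)

    pair = (a * 4 + b)               # (B, S)
    jj = np.repeat(np.arange(B), n_sites)
    total = cum[-1, jj, pair.ravel()]
    w0 = np.where((a == b).ravel(), np.exp(-m)[jj], 0.0)
    # shortcut: most cells have no uniformized jump at all
    u = rng.random(B * n_sites) * total
    hot = np.flatnonzero(u >= w0)
    np.add.at(dwell, (1 + jj[u < w0], a.ravel()[u < w0]), 1.0)

    if hot.size:
        cum_hot = cum[:, jj[hot], pair.ravel()[hot]]   # (n_top+1, C)
        N = (cum_hot < u[hot][None, :]).sum(axis=0)
        branch = 1 + jj[hot]
        ah = a.ravel()[hot]
        bh = b.ravel()[hot]
        flat_counts = counts.reshape(n_nodes, 16)
        for n in np.unique(N):
            sel = np.flatnonzero(N == n)
            c = sel.size
            path = np.empty((c, n + 1), dtype=np.int64)
            path[:, 0] = ah[sel]
            path[:, n] = bh[sel]
            bsel = bh[sel]
            for k in range(1, n):
                probs = R[path[:, k - 1]] * Rpow[n - k][:, bsel].T
                path[:, k] = _sample_categorical(probs, rng)
            prev = path[:, :-1]
            nxt = path[:, 1:]
            chg = prev != nxt        # real (non-virtual) jumps
            if np.any(chg):
                br = np.broadcast_to(branch[sel, None], prev.shape)[chg]
                np.add.at(flat_counts, (br, prev[chg] * 4 + nxt[chg]), 1.0)
            # dwell fractions: spacings of n uniforms = Dirichlet(1, ..., 1)
            e = rng.standard_exponential((c, n + 1))
            frac = e / e.sum(axis=1, keepdims=True)
            br_all = np.broadcast_to(branch[sel, None], path.shape)
            np.add.at(dwell, (br_all.ravel(), path.ravel()), frac.ravel())

    return SuffStats(counts, dwell, n_sites, root_counts)
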