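"""General time-reversible nucleotide substitution model.

The generator is parametrized by six relative exchangeabilities and four
equilibrium frequencies, both on the unit simplex (uniform Dirichlet priors
in the sampler), and is normalized to one expected substitution per unit of
effective branch length.  Matrix exponentials use the symmetric
eigendecomposition of the reversible generator (pi^{1/2} similarity
transform), so one eigensystem serves every branch.

No among-site or among-partition rate variation is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Alignment
from .timetree import TimeTree

__all__ = ["GTRParams", "RateMatrix", "build_gtr", "transition_probs",
           "pruning_loglik", "simulate_sequences"]

# pair order of the exchangeability vector
PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class GTRParams:
    """Exchangeabilities (AC, AG, AT, CG, CT, GT) and frequencies (A, C, G, T)."""

    rho: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        for v, k, name in ((self.rho, 6, "rho"), (self.pi, 4, "pi")):
            if v.shape != (k,):
                raise ValueError(f"{name} must have length {k}")
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be a point on the simplex")

    @classmethod
    def jc(cls) -> "GTRParams":
        return cls(np.full(6, 1 / 6), np.full(4, 0.25))


class RateMatrix:
    """Normalized reversible generator with a cached eigensystem.

    Attributes
    ----------
    Q : (4, 4) generator, rows summing to zero, -sum_a pi_a Q_aa = 1.
    pi : stationary frequencies.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        self.pi = pi
        sq = np.sqrt(pi)
        sym = (Q * sq[:, None]) / sq[None, :]
        evals, evecs = np.linalg.eigh(0.5 * (sym + sym.T))
        # columns of left/right transforms: P(l) = right @ diag(exp(evals*l)) @ left
        # generator eigenvalues are <= 0; clip float noise on the null eigenvalue
        self._evals = np.minimum(evals, 0.0)
        self._right = evecs / sq[:, None]
        self._left = evecs.T * sq[None, :]
        self.omega = float(np.max(-np.diag(Q)))

    def transition_probs(self, lengths) -> np.ndarray:
        """Transition matrices for one or many effective lengths.

        Returns shape (4, 4) for a scalar length and (n, 4, 4) for a vector.
        """
        l = np.asarray(lengths, dtype=float)
        if np.any(l < 0):
            raise ValueError("effective lengths must be >= 0")
        e = np.exp(np.multiply.outer(l, self._evals))  # (..., 4)
        P = np.einsum("ik,...k,kj->...ij", self._right, e, self._left)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=-1, keepdims=True)
        return P


def build_gtr(params: GTRParams) -> RateMatrix:
    """Assemble the normalized GTR generator Q_ab = rho_ab * pi_b."""
    if np.any(params.pi <= 0):
        raise ValueError("GTR requires strictly positive equilibrium frequencies")
    Q = np.zeros((4, 4))
    for r, (a, b) in zip(params.rho, PAIRS):
        Q[a, b] = r * params.pi[b]
        Q[b, a] = r * params.pi[a]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(params.pi @ np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate GTR generator (zero total rate)")
    return RateMatrix(Q / scale, params.pi)


def transition_probs(Q: RateMatrix, length: float) -> np.ndarray:
    """4x4 stochastic matrix for a branch of the given effective length."""
    return Q.transition_probs(float(length))


def _tip_masks_in_tree_order(tree: TimeTree, aln: Alignment) -> np.ndarray:
    aln.check_against_tree(tree)
    masks = aln.masks()
    row = {lab: i for i, lab in enumerate(aln.labels)}
    out = np.zeros((tree.n_nodes, aln.n_sites, 4))
    for v in tree.tips:
        out[v] = masks[row[tree.labels[v]]]
    return out


def pruning_loglik(tree: TimeTree, lengths: np.ndarray, aln: Alignment,
                   Q: RateMatrix) -> float:
    """Felsenstein-pruning log-likelihood.

    ``lengths`` holds effective branch lengths indexed by child node
    (entry 0, the root, is ignored).  Ambiguity codes act as partial
    likelihood masks; by reversibility the result is invariant to where the
    root is placed along any branch.
    """
    partial, scale = _pruning_pass(tree, lengths, aln, Q)
    site_like = partial[0] @ Q.pi
    if np.any(site_like <= 0):
        return -np.inf
    return float(np.sum(np.log(site_like) + scale[0]))


def _pruning_pass(tree: TimeTree, lengths, aln, Q, tip_masks=None):
    """Bottom-up partial likelihoods with per-site log scalers."""
    lengths = np.asarray(lengths, dtype=float)
    P = Q.transition_probs(lengths)  # (n_nodes, 4, 4); row 0 unused
    partial = (_tip_masks_in_tree_order(tree, aln) if tip_masks is None
               else tip_masks.copy())
    scale = np.zeros((tree.n_nodes, aln.n_sites))
    for v in tree.postorder():
        if tree.is_tip[v]:
            continue
        c0, c1 = tree.children[v]
        vals = (partial[c0] @ P[c0].T) * (partial[c1] @ P[c1].T)
        s = vals.max(axis=1)
        s[s == 0] = 1.0
        partial[v] = vals / s[:, None]
        scale[v] = scale[c0] + scale[c1] + np.log(s)
    return partial, scale


def simulate_sequences(tree: TimeTree, lengths, Q: RateMatrix, n_sites: int,
                       rng: np.random.Generator) -> Alignment:
    """Evolve ``n_sites`` independent sites down the tree under the GTR model."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    lengths = np.asarray(lengths, dtype=float)
    P = Q.transition_probs(lengths)
    states = np.zeros((tree.n_nodes, n_sites), dtype=np.int64)
    states[0] = rng.choice(4, size=n_sites, p=Q.pi)
    for v in range(1, tree.n_nodes):
        probs = P[v][states[tree.parent[v]]]  # (n_sites, 4)
        u = rng.random(n_sites)
        states[v] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    tips = tree.tips
    return Alignment.from_states([tree.labels[v] for v in tips], states[tips])
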