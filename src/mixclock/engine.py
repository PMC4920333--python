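"""MCMC engine for Bayesian dating under Brownian, white-noise and mixed clocks.

A sampling cycle alternates a Gibbs refresh of the substitution histories
(stochastic mapping) with sweeps of Metropolis-Hastings updates over node
ages, fossil tip ages, node log-rates, branch multipliers, clock and
tree-prior hyperparameters and the GTR parameters, all conditional on the
mapping's sufficient statistics.  A compensatory move rescales the Brownian
and white-noise components of the mixed clock in opposite directions,
leaving every effective branch length (hence the likelihood) untouched.

Updates within a sweep are vectorized over conditionally independent blocks
(nodes of equal topological depth parity never share an edge, so their local
posteriors factorize).  The engine can also run with the exact pruning
likelihood recomputed per update (``likelihood="pruning"``; used for
cross-validating the augmented scheme) or with no data at all
(``likelihood="none"``; used for prior-sampling checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import clocks, time_priors
from .clocks import SIGMA_B_RANGE, X0_RANGE
from .gtr import GTRParams, build_gtr, pruning_loglik
from .io import Alignment
from .mapping import sample_mapping, suffstat_loglik
from .timetree import TimeTree, MIN_AGE_GAP

__all__ = ["RunConfig", "ChainResult", "MixedClockSampler", "run_chain",
           "tracecomp", "ess"]

log = logging.getLogger("mixclock")


@dataclass
class RunConfig:
    """Sampler configuration; defaults follow the published analysis settings."""

    clock: str = "mixed"          # bm | wn | mixed
    mode: str = "node"            # node | tip
    n_cycles: int = 21000         # total cycles, burn-in included
    burnin: int = 1000
    thin: int = 1
    sweeps_per_cycle: int = 10    # full MH sweeps per cycle
    refresh_every: int = 1        # mapping refreshes every k-th cycle
    seed: int = 0
    likelihood: str = "augmented"  # augmented | pruning | none
    tc: float = 25.0              # serial-BD cut-off time (Myr)
    ntot: int = 5000              # total extant diversity behind the cut-off
    use_ntot: bool = True
    # hyperprior means (exponential priors)
    prior_d_mean: float = 1.0
    prior_b_mean: float = 1.0
    prior_mu_mean: float = 10.0
    prior_psi_mean: float = 1.0
    prior_root_mean: float = 100.0
    prior_sigma2w_mean: float = 1.0
    prior_muw_mean: float = 1.0

    def __post_init__(self):
        if self.clock not in ("bm", "wn", "mixed"):
            raise ValueError(f"unknown clock {self.clock!r}")
        if self.mode not in ("node", "tip"):
            raise ValueError(f"unknown dating mode {self.mode!r}")
        if self.likelihood not in ("augmented", "pruning", "none"):
            raise ValueError(f"unknown likelihood mode {self.likelihood!r}")
        for name in ("n_cycles", "burnin", "thin", "sweeps_per_cycle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("tc", "prior_d_mean", "prior_b_mean", "prior_mu_mean",
                     "prior_psi_mean", "prior_root_mean", "prior_sigma2w_mean",
                     "prior_muw_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ChainResult:
    trace: pd.DataFrame
    config: RunConfig
    age_samples: np.ndarray       # (n_samples, n_nodes)
    x_samples: np.ndarray | None  # (n_samples, n_nodes) log-rates (bm/mixed)
    r_samples: np.ndarray | None  # (n_samples, n_nodes) multipliers (wn/mixed)
    sampler: "MixedClockSampler"

    def summary_ages(self, cred=0.95) -> pd.DataFrame:
        lo = (1 - cred) / 2
        q = np.quantile(self.age_samples, [0.5, lo, 1 - lo], axis=0)
        return pd.DataFrame({"median": q[0], "lower": q[1], "upper": q[2]})


class MixedClockSampler:
    """Data-augmented Metropolis-within-Gibbs sampler on a fixed topology."""

    def __init__(self, tree: TimeTree, aln: Alignment | None, config: RunConfig,
                 calibrations: dict | None = None,
                 fossil_intervals: dict | None = None,
                 rng: np.random.Generator | None = None,
                 gtr: GTRParams | None = None):
        self.cfg = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.tree = tree.copy()
        self.aln = aln
        if config.likelihood != "none" and aln is None:
            raise ValueError("an alignment is required unless likelihood='none'")
        if aln is not None:
            aln.check_against_tree(self.tree)
        if config.mode == "node" and np.any(self.tree.fossil):
            raise ValueError("node-dating requires an ultrametric extant tree")

        n = self.tree.n_nodes
        self._par = self.tree.parent.copy()
        self._par[0] = 0  # safe padding for vectorized gathers
        self._kids = self.tree.children
        self._is_tip = self.tree.is_tip
        self._fossil_mask = self.tree.fossil & self._is_tip
        self._fossil_tips = np.flatnonzero(self._fossil_mask)

        # calibration bounds, node-indexed
        self.bounds_lo = np.zeros(n)
        self.bounds_hi = np.full(n, np.inf)
        for v, (lo, hi) in (calibrations or {}).items():
            if lo is not None:
                self.bounds_lo[v] = lo
            if hi is not None:
                self.bounds_hi[v] = hi
        # fossil age intervals, node-indexed
        if fossil_intervals:
            lab2node = self.tree.tip_label_to_node
            for lab, (lo, hi) in fossil_intervals.items():
                v = lab2node[lab]
                if not self.tree.fossil[v]:
                    raise ValueError(f"{lab!r} is not a fossil tip")
                self.bounds_lo[v] = max(self.bounds_lo[v], lo)
                self.bounds_hi[v] = min(self.bounds_hi[v], hi)
        if config.mode == "tip":
            internal = self.tree.internal
            self.bounds_lo[internal] = np.maximum(self.bounds_lo[internal], config.tc)
            self.bounds_lo[self._fossil_tips] = np.maximum(
                self.bounds_lo[self._fossil_tips], config.tc)

        # conditionally independent update blocks by depth parity
        depth = self.tree.depths()
        nonroot_int = np.flatnonzero(~self._is_tip)
        nonroot_int = nonroot_int[nonroot_int != 0]
        self._age_blocks = [nonroot_int[depth[nonroot_int] % 2 == p] for p in (0, 1)]
        allnodes = np.arange(n)
        self._x_blocks = [allnodes[(depth % 2 == p) & (allnodes != 0)] for p in (0, 1)]

        self._init_state(gtr)
        self._init_proposals()
        self._reset_trace()
        self.cycle = 0
        self._adapting = True

    # ------------------------------------------------------------------
    # initialization
    # ------------------------------------------------------------------
    def _init_state(self, gtr):
        cfg = self.cfg
        n = self.tree.n_nodes
        self._repair_ages()
        self.sigma2_b = 0.05
        self.sigma2_w = 0.1
        x0 = self._init_x0()
        # the mean rate is carried by x(0) (bm/mixed) or mu_w (wn)
        self.mu_w = float(np.exp(x0)) if cfg.clock == "wn" else 1.0
        self.x = np.full(n, x0)
        # white-noise multipliers live in log space (tiny gamma shapes
        # underflow linear doubles); Rm = exp(logR) is a derived cache
        self.logR = np.zeros(n)
        self.Rm = np.ones(n)
        if gtr is None:
            pi = self._empirical_freqs()
            gtr = GTRParams(np.full(6, 1 / 6), pi)
        self.gtr = gtr
        self.Q = build_gtr(gtr)
        if cfg.mode == "node":
            self.bd = time_priors.NodeBDParams(d=0.1, b=0.1)
        else:
            self.bd = time_priors.SerialBDParams(d=0.05, mu=0.05, psi=0.02,
                                                 t_c=cfg.tc, n_tot=cfg.ntot)
        self._refresh_caches()
        self._tip_masks = None
        self.suff = None
        self._ss_ntot = np.zeros(n)
        self._ss_nlogq = np.zeros(n)
        self._ss_wq = np.zeros(n)
        self._ss_Nab = np.zeros((4, 4))
        if cfg.likelihood == "augmented":
            self.gibbs_refresh_mapping()

    def _empirical_freqs(self) -> np.ndarray:
        if self.aln is None:
            return np.full(4, 0.25)
        masks = self.aln.masks()
        unambig = masks.sum(axis=2) == 1
        counts = masks[unambig].sum(axis=0) + 1.0
        return counts / counts.sum()

    def _init_x0(self) -> float:
        """Crude strict-clock rate from average tip divergence (JC-corrected)."""
        if self.aln is None:
            return 0.0
        codes = self.aln.codes
        k = codes.shape[0]
        rng = np.random.default_rng(0)
        pairs = [(i, (i + 1) % k) for i in range(min(k, 20))]
        ps = []
        for i, j in pairs:
            det = (np.bincount(codes[i], minlength=16)[[1, 2, 4, 8]].sum() > 0)
            both = (np.isin(codes[i], (1, 2, 4, 8)) & np.isin(codes[j], (1, 2, 4, 8)))
            if both.sum() == 0:
                continue
            ps.append(np.mean(codes[i][both] != codes[j][both]))
        p = float(np.clip(np.mean(ps) if ps else 0.1, 1e-4, 0.70))
        d = -0.75 * np.log(max(1.0 - 4.0 * p / 3.0, 1e-3))
        depth = float(np.mean(self.tree.ages[self.tree.internal]))
        return float(np.log(max(d / max(2.0 * depth, 1e-8), 1e-8)))

    def _repair_ages(self) -> None:
        """Adjust node ages to a configuration satisfying all hard constraints."""
        tree = self.tree
        ages = tree.ages
        # strict floor from descendants; lower calibration bounds are >=
        floor = np.zeros(tree.n_nodes)
        for v in tree.postorder():
            if self._is_tip[v]:
                if tree.fossil[v]:
                    ages[v] = float(np.clip(ages[v], self.bounds_lo[v],
                                            self.bounds_hi[v]))
                floor[v] = ages[v]
            else:
                floor[v] = max(floor[tree.children[v, 0]],
                               floor[tree.children[v, 1]]) + 10 * MIN_AGE_GAP

        def feasible(v):
            hi = self.bounds_hi[v] if v == 0 else min(self.bounds_hi[v],
                                                      ages[tree.parent[v]])
            return (ages[v] > floor[v] - 10 * MIN_AGE_GAP
                    and self.bounds_lo[v] <= ages[v] <= hi
                    and (v == 0 or ages[v] < ages[tree.parent[v]]))

        if all(feasible(v) for v in tree.internal):
            return
        # rebuild top-down: place each node between its floor and its ceiling
        lo0 = max(floor[0], self.bounds_lo[0])
        ages[0] = min(max(1.25 * lo0, lo0 + 5.0), self.bounds_hi[0])
        if ages[0] < lo0 or ages[0] <= floor[0]:
            raise ValueError("infeasible calibration set at the root")
        order = np.argsort(tree.depths())
        for v in order:
            if v == 0 or self._is_tip[v]:
                continue
            p = tree.parent[v]
            lo = max(floor[v], self.bounds_lo[v])
            hi = min(ages[p] - MIN_AGE_GAP, self.bounds_hi[v])
            if hi < lo:
                raise ValueError(f"infeasible age constraints at node {v}")
            ages[v] = lo + 0.75 * (hi - lo)

    def _init_proposals(self) -> None:
        scale = max(self.tree.root_age / 20.0, 1.0)
        self._delta = {
            "age": scale, "root": scale, "fossil": scale, "x": 0.5, "x0": 0.5,
            "R": 0.5, "comp": 0.4, "sigma2_b": 1.0, "sigma2_w": 1.0, "mu_w": 0.5,
            "bd_d": 0.8, "bd_b": 0.8, "bd_mu": 0.8, "bd_psi": 0.8,
            "rho_c": 300.0, "pi_c": 300.0,
            "x0t": 1.0, "xr": 1.0, "Rr": 1.0, "ageu": 1.0,  # independence moves
            "tscale": 0.3, "xswap": 0.6, "bscale": 1.5, "wnscale": 0.5,
        }
        self._acc = {k: [0, 0] for k in self._delta}

    def _reset_trace(self) -> None:
        self._records: list[dict] = []
        self._ages_out: list[np.ndarray] = []
        self._x_out: list[np.ndarray] = []
        self._r_out: list[np.ndarray] = []

    # ------------------------------------------------------------------
    # cached derived quantities
    # ------------------------------------------------------------------
    def _refresh_caches(self) -> None:
        ages = self.tree.ages
        self.dt = np.ones(self.tree.n_nodes)
        self.dt[1:] = ages[self._par[1:]] - ages[1:]
        self.rho = np.ones(self.tree.n_nodes)
        if self.cfg.clock in ("bm", "mixed"):
            er = np.exp(self.x)
            self.rho[1:] = 0.5 * (er[self._par[1:]] + er[1:])
        if self.cfg.clock in ("wn", "mixed"):
            self.rho[1:] = self.rho[1:] * self.Rm[1:] if self.cfg.clock == "mixed" \
                else self.Rm[1:]
        self.ell = np.zeros(self.tree.n_nodes)
        self.ell[1:] = self.dt[1:] * self.rho[1:]
        self._plik = None

    @property
    def _use_bm(self) -> bool:
        return self.cfg.clock in ("bm", "mixed")

    @property
    def _use_wn(self) -> bool:
        return self.cfg.clock in ("wn", "mixed")

    # ------------------------------------------------------------------
    # likelihood pieces
    # ------------------------------------------------------------------
    def gibbs_refresh_mapping(self) -> None:
        """Gibbs draw of substitution histories; parameters are untouched."""
        if self._tip_masks is None:
            from .gtr import _tip_masks_in_tree_order
            self._tip_masks = _tip_masks_in_tree_order(self.tree, self.aln)
        self.suff = sample_mapping(self.tree, self.ell, self.aln, self.Q, self.rng,
                                   tip_masks=self._tip_masks)
        self._cache_suff_terms()

    def _cache_suff_terms(self) -> None:
        self._ss_ntot, self._ss_nlogq, self._ss_wq = self.suff.branch_terms(self.Q)
        self._ss_Nab = self.suff.counts.sum(axis=0)

    def loglik(self) -> float:
        if self.cfg.likelihood == "none":
            return 0.0
        if self.cfg.likelihood == "pruning":
            return pruning_loglik(self.tree, self.ell, self.aln, self.Q)
        return suffstat_loglik(self.suff, self.Q, self.ell)

    def _aug_term(self, j, ell):
        """Length-dependent part of the augmented log-likelihood on branches j."""
        if self.cfg.likelihood != "augmented":
            return np.zeros_like(np.asarray(ell, dtype=float))
        ell = np.asarray(ell, dtype=float)
        if np.any(ell <= 0):  # underflowed length: impossible unless eventless
            with np.errstate(divide="ignore", invalid="ignore"):
                t = self._ss_ntot[j] * np.log(ell) + ell * self._ss_wq[j]
            return np.where((ell <= 0) & (self._ss_ntot[j] > 0), -np.inf,
                            np.where(ell <= 0, 0.0, t))
        return self._ss_ntot[j] * np.log(ell) + ell * self._ss_wq[j]

    # ------------------------------------------------------------------
    # prior pieces
    # ------------------------------------------------------------------
    def _bm_edge_term(self, j, dt, xdiff2):
        v = self.sigma2_b * dt
        return -0.5 * np.log(2 * np.pi * v) - xdiff2 / (2 * v)

    def _wn_edge_term(self, j, dt, logRv):
        """Gamma log-density of a multiplier, parametrized by its log."""
        a = self.mu_w**2 * dt / self.sigma2_w
        b = self.mu_w * dt / self.sigma2_w
        return a * np.log(b) - gammaln(a) + (a - 1) * logRv - b * np.exp(logRv)

    def _branch_terms(self, jmat, dtmat, ellmat, mask):
        """Sum over the branch matrix of likelihood+clock-prior edge terms."""
        out = self._aug_term(jmat, ellmat)
        if self._use_bm:
            xd2 = (self.x[jmat] - self.x[self._par[jmat]]) ** 2
            out = out + self._bm_edge_term(jmat, dtmat, xd2)
        if self._use_wn:
            out = out + self._wn_edge_term(jmat, dtmat, self.logR[jmat])
        return np.where(mask, out, 0.0).sum(axis=1)

    def _time_node_terms(self, v, t):
        """Per-node time-prior terms (parts that depend on this node's age)."""
        t = np.asarray(t, dtype=float)
        out = np.where((t >= self.bounds_lo[v]) & (t <= self.bounds_hi[v]), 0.0, -np.inf)
        if self.cfg.mode == "node":
            out = out + time_priors.log_p1(t, self.bd.d, self.bd.b)
        else:
            z = t - self.cfg.tc
            bad = z <= 0
            zs = np.where(bad, 1.0, z)
            lq = time_priors.log_q(zs, self.bd.lam, self.bd.mu, self.bd.psi)
            sign = np.where(self._fossil_mask[v], -1.0, 1.0)
            out = out + np.where(bad, -np.inf, sign * lq)
        return out

    def time_logprior(self) -> float:
        """Full log-prior over divergence times, hyperpriors included."""
        tree, cfg = self.tree, self.cfg
        ages = tree.ages
        if np.any(ages < self.bounds_lo) or np.any(ages > self.bounds_hi):
            return -np.inf
        lp = -ages[0] / cfg.prior_root_mean - np.log(cfg.prior_root_mean)
        if cfg.mode == "node":
            lp += time_priors.node_bd_logdensity(tree, self.bd, bounds=None,
                                                 include_hyper=False)
            lp += -self.bd.d / cfg.prior_d_mean - np.log(cfg.prior_d_mean)
            lp += -self.bd.b / cfg.prior_b_mean - np.log(cfg.prior_b_mean)
        else:
            lp += time_priors.serial_bd_logdensity(
                tree, self.bd, include_ntot=cfg.use_ntot)
            lp += -self.bd.d / cfg.prior_d_mean - np.log(cfg.prior_d_mean)
            lp += -self.bd.mu / cfg.prior_mu_mean - np.log(cfg.prior_mu_mean)
            lp += -self.bd.psi / cfg.prior_psi_mean - np.log(cfg.prior_psi_mean)
        return float(lp)

    def clock_logprior(self) -> float:
        lp = 0.0
        if self._use_bm:
            st = clocks.BrownianState(self.x, self.sigma2_b)
            lp += clocks.bm_logprior(st, self.tree, include_hyper=True)
        if self._use_wn:
            lp += self._wn_prior_full()
        return lp

    def logprior(self) -> float:
        return self.clock_logprior() + self.time_logprior()

    # ------------------------------------------------------------------
    # move bookkeeping
    # ------------------------------------------------------------------
    def _tally(self, name, accepted, proposed) -> None:
        self._acc[name][0] += int(accepted)
        self._acc[name][1] += int(proposed)

    def _adapt(self) -> None:
        for name, (a, p) in self._acc.items():
            if p < 20 or name in ("x0t", "xr", "Rr", "ageu"):
                continue
            rate = a / p
            step = float(np.exp(0.66 * (rate - 0.3)))
            if name in ("rho_c", "pi_c"):
                self._delta[name] = float(np.clip(self._delta[name] / step, 10.0, 1e6))
            else:
                self._delta[name] = float(np.clip(self._delta[name] * step, 1e-4, 1e4))
            self._acc[name] = [0, 0]

    def _metropolis_mask(self, logratio) -> np.ndarray:
        logratio = np.asarray(logratio, dtype=float)
        # NaN compares False, so invalid proposals are rejected automatically
        return np.log(self.rng.random(logratio.shape)) < logratio

    # ------------------------------------------------------------------
    # block moves
    # ------------------------------------------------------------------
    def _jmat_for_nodes(self, V):
        """(len(V), 3) branch matrix [own, child0, child1] with validity mask."""
        V = np.asarray(V)
        jmat = np.zeros((V.size, 3), dtype=np.int64)
        mask = np.zeros((V.size, 3), dtype=bool)
        jmat[:, 0] = V
        mask[:, 0] = V != 0
        kids = self._kids[V]
        has_kids = kids[:, 0] >= 0
        jmat[:, 1:] = np.where(kids >= 0, kids, 0)
        mask[:, 1] = has_kids
        mask[:, 2] = has_kids
        return jmat, mask

    def move_ages_block(self, V) -> None:
        if V.size == 0:
            return
        ages = self.tree.ages
        t = ages[V]
        tprop = t + self.rng.uniform(-self._delta["age"], self._delta["age"], V.size)
        kids = self._kids[V]
        floor = np.maximum(ages[kids[:, 0]], ages[kids[:, 1]]) + MIN_AGE_GAP
        ceil = ages[self.tree.parent[V]] - MIN_AGE_GAP
        valid = (tprop > floor) & (tprop < ceil)
        jmat, mask = self._jmat_for_nodes(V)
        dt_now = np.column_stack([ages[self._par[V]] - t, t - ages[kids[:, 0]],
                                  t - ages[kids[:, 1]]])
        dt_new = np.column_stack([ages[self._par[V]] - tprop,
                                  tprop - ages[kids[:, 0]], tprop - ages[kids[:, 1]]])
        dt_new = np.where(valid[:, None], dt_new, 1.0)
        rho = self.rho[jmat]
        before = self._branch_terms(jmat, dt_now, dt_now * rho, mask) \
            + self._time_node_terms(V, t)
        after = self._branch_terms(jmat, dt_new, dt_new * rho, mask) \
            + self._time_node_terms(V, tprop)
        logr = np.where(valid, after - before, -np.inf)
        if self.cfg.likelihood == "pruning" and np.isfinite(logr[0]):
            logr = logr + self._pruning_extra(jmat[0][mask[0]],
                                              (dt_new * rho)[0][mask[0]])
        acc = self._metropolis_mask(logr)
        ages[V[acc]] = tprop[acc]
        self._tally("age", acc.sum(), V.size)
        if np.any(acc):
            self._refresh_dt_ell(np.unique(jmat[acc][mask[acc]]))

    def move_ages_uniform_block(self, V) -> None:
        """Independence age proposals, uniform on the current (floor, ceil).

        The window depends only on neighbours (fixed within a block), so the
        proposal density cancels; complements the local random walk by
        jumping across the short-branch funnel of the Brownian prior.
        """
        if V.size == 0:
            return
        ages = self.tree.ages
        t = ages[V]
        kids = self._kids[V]
        floor = np.maximum(ages[kids[:, 0]], ages[kids[:, 1]]) + MIN_AGE_GAP
        ceil = ages[self.tree.parent[V]] - MIN_AGE_GAP
        ok = ceil > floor
        tprop = np.where(ok, floor + self.rng.random(V.size) * (ceil - floor), t)
        jmat, mask = self._jmat_for_nodes(V)
        dt_now = np.column_stack([ages[self._par[V]] - t, t - ages[kids[:, 0]],
                                  t - ages[kids[:, 1]]])
        dt_new = np.column_stack([ages[self._par[V]] - tprop,
                                  tprop - ages[kids[:, 0]],
                                  tprop - ages[kids[:, 1]]])
        dt_new = np.where(ok[:, None], dt_new, 1.0)
        rho = self.rho[jmat]
        before = self._branch_terms(jmat, dt_now, dt_now * rho, mask) \
            + self._time_node_terms(V, t)
        after = self._branch_terms(jmat, dt_new, dt_new * rho, mask) \
            + self._time_node_terms(V, tprop)
        logr = np.where(ok, after - before, -np.inf)
        if self.cfg.likelihood == "pruning" and np.isfinite(logr[0]):
            logr = logr + self._pruning_extra(jmat[0][mask[0]],
                                              (dt_new * rho)[0][mask[0]])
        acc = self._metropolis_mask(logr)
        ages[V[acc]] = tprop[acc]
        self._tally("ageu", acc.sum(), V.size)
        if np.any(acc):
            self._refresh_dt_ell(np.unique(jmat[acc][mask[acc]]))

    def _refresh_dt_ell(self, js) -> None:
        js = js[js != 0]
        ages = self.tree.ages
        self.dt[js] = ages[self._par[js]] - ages[js]
        self.ell[js] = self.dt[js] * self.rho[js]
        self._plik = None

    # ---- exact-likelihood support for likelihood="pruning" -----------
    def _pruning_cached(self) -> float:
        if self._plik is None:
            self._plik = pruning_loglik(self.tree, self.ell, self.aln, self.Q)
        return self._plik

    def _pruning_extra(self, js, ell_new) -> float:
        """Likelihood delta for proposed lengths on branches js."""
        ell_prop = self.ell.copy()
        ell_prop[js] = ell_new
        after = pruning_loglik(self.tree, ell_prop, self.aln, self.Q)
        return after - self._pruning_cached()

    def move_root_age(self) -> None:
        cfg = self.cfg
        ages = self.tree.ages
        t = ages[0]
        tprop = t + self.rng.uniform(-self._delta["root"], self._delta["root"])
        kids = self._kids[0]
        floor = max(ages[kids[0]], ages[kids[1]]) + MIN_AGE_GAP
        ok = (tprop > floor and self.bounds_lo[0] <= tprop <= self.bounds_hi[0])
        if ok:
            jmat = kids[None, :]
            mask = np.ones((1, 2), dtype=bool)
            dt_now = (t - ages[kids])[None, :]
            dt_new = (tprop - ages[kids])[None, :]
            rho = self.rho[jmat]
            delta = (self._branch_terms(jmat, dt_new, dt_new * rho, mask)
                     - self._branch_terms(jmat, dt_now, dt_now * rho, mask))[0]
            delta += (t - tprop) / cfg.prior_root_mean
            if cfg.mode == "node":
                n_free = self.tree.internal.size - 1
                delta += n_free * (np.log(time_priors.cum_p1(t, self.bd.d, self.bd.b))
                                   - np.log(time_priors.cum_p1(tprop, self.bd.d,
                                                               self.bd.b)))
            else:
                lam, mu, psi = self.bd.lam, self.bd.mu, self.bd.psi
                for tt, sgn in ((tprop, 1.0), (t, -1.0)):
                    z = tt - cfg.tc
                    if z <= 0:
                        delta = -np.inf
                        break
                    delta += sgn * (2 * time_priors.log_q(z, lam, mu, psi)
                                    - 2 * np.log1p(-time_priors.p0(z, lam, mu, psi)))
            if self.cfg.likelihood == "pruning" and np.isfinite(delta):
                delta += self._pruning_extra(kids, (dt_new * rho)[0])
            acc = bool(self._metropolis_mask(delta))
        else:
            acc = False
        if acc:
            ages[0] = tprop
            self._refresh_dt_ell(kids.copy())
        self._tally("root", acc, 1)

    def move_tree_scale(self) -> None:
        """Multiplicative rescaling of every mobile age (root, internal,
        fossil tips); Jacobian c^k for k scaled ages."""
        u = self.rng.uniform(-self._delta["tscale"], self._delta["tscale"])
        c = np.exp(u)
        mobile = np.concatenate([self.tree.internal, self._fossil_tips])
        ages_old = self.tree.ages.copy()
        dt_old, ell_old = self.dt.copy(), self.ell.copy()
        before = self.time_logprior() + self._clock_edge_sum()
        self.tree.ages[mobile] *= c
        self._refresh_caches()
        after = self.time_logprior() + self._clock_edge_sum()
        if self.cfg.likelihood == "augmented":
            J = self.tree.branches
            after += float(np.sum(self._aug_term(J, self.ell[J])
                                  - self._aug_term(J, ell_old[J])))
        elif self.cfg.likelihood == "pruning":
            after += pruning_loglik(self.tree, self.ell, self.aln, self.Q)
            before += pruning_loglik(self.tree, ell_old, self.aln, self.Q)
        acc = bool(self._metropolis_mask(after - before + mobile.size * u))
        if not acc:
            self.tree.ages = ages_old
            self.dt, self.ell = dt_old, ell_old
        self._tally("tscale", acc, 1)

    def _clock_edge_sum(self) -> float:
        J = self.tree.branches
        out = 0.0
        if self._use_bm:
            xd2 = (self.x[J] - self.x[self._par[J]]) ** 2
            out += float(np.sum(self._bm_edge_term(J, self.dt[J], xd2)))
        if self._use_wn:
            out += float(np.sum(self._wn_edge_term(J, self.dt[J], self.logR[J])))
        return out

    def move_fossil_ages(self, V=None) -> None:
        V = self._fossil_tips if V is None else V
        if V.size == 0:
            return
        if self.cfg.likelihood == "pruning" and V.size > 1:
            for v in V:  # exact mode: one fossil at a time
                self.move_fossil_ages(np.array([v]))
            return
        ages = self.tree.ages
        t = ages[V]
        tprop = t + self.rng.uniform(-self._delta["fossil"], self._delta["fossil"],
                                     V.size)
        ceil = ages[self.tree.parent[V]] - MIN_AGE_GAP
        valid = (tprop < ceil) & (tprop > 0)
        jmat = V[:, None]
        mask = np.ones_like(jmat, dtype=bool)
        dt_now = (ages[self._par[V]] - t)[:, None]
        dt_new = np.where(valid, ages[self._par[V]] - tprop, 1.0)[:, None]
        rho = self.rho[jmat]
        before = self._branch_terms(jmat, dt_now, dt_now * rho, mask) \
            + self._time_node_terms(V, t)
        after = self._branch_terms(jmat, dt_new, dt_new * rho, mask) \
            + self._time_node_terms(V, tprop)
        logr = np.where(valid, after - before, -np.inf)
        if self.cfg.likelihood == "pruning" and np.isfinite(logr[0]):
            logr = logr + self._pruning_extra(V, (dt_new * rho)[0])
        acc = self._metropolis_mask(logr)
        ages[V[acc]] = tprop[acc]
        self._tally("fossil", acc.sum(), V.size)
        if np.any(acc):
            self._refresh_dt_ell(V[acc])

    def move_x_block(self, V) -> None:
        if V.size == 0 or not self._use_bm:
            return
        xs = self.x
        xv = xs[V]
        xprop = xv + self.rng.uniform(-self._delta["x"], self._delta["x"], V.size)
        jmat, mask = self._jmat_for_nodes(V)
        dt = self.dt[jmat]
        Rfac = self.Rm[jmat] if self.cfg.clock == "mixed" else 1.0

        def terms(xval, return_ell=False):
            xfull_v = xval  # value at V
            # branch endpoint values: own branch (V child): up=parent (fixed), dn=V
            xpar = xs[self._par[jmat]]
            xdn = xs[jmat]
            # replace entries where endpoint is the moving node
            own = jmat == V[:, None]
            par_is_v = self._par[jmat] == V[:, None]
            xdn = np.where(own, xfull_v[:, None], xdn)
            xpar = np.where(par_is_v, xfull_v[:, None], xpar)
            rates = 0.5 * (np.exp(xpar) + np.exp(xdn))
            ell = dt * rates * Rfac
            out = self._aug_term(jmat, ell) + self._bm_edge_term(
                jmat, dt, (xdn - xpar) ** 2)
            out = np.where(mask, out, 0.0).sum(axis=1)
            return (out, ell) if return_ell else out

        if self.cfg.likelihood == "pruning":
            after, ell_new = terms(xprop, return_ell=True)
            logr = after - terms(xv)
            logr = logr + self._pruning_extra(jmat[0][mask[0]], ell_new[0][mask[0]])
        else:
            logr = terms(xprop) - terms(xv)
        acc = self._metropolis_mask(logr)
        accV = V[acc]
        xs[accV] = xprop[acc]
        self._tally("x", acc.sum(), V.size)
        if np.any(acc):
            self._recompute_rho(np.unique(jmat[acc][mask[acc]]))

    def _recompute_rho(self, js) -> None:
        js = js[js != 0]
        if self.cfg.clock == "bm":
            self.rho[js] = 0.5 * (np.exp(self.x[self._par[js]]) + np.exp(self.x[js]))
        elif self.cfg.clock == "mixed":
            self.rho[js] = 0.5 * (np.exp(self.x[self._par[js]])
                                  + np.exp(self.x[js])) * self.Rm[js]
        else:
            self.rho[js] = self.Rm[js]
        self.ell[js] = self.dt[js] * self.rho[js]
        self._plik = None

    def _ell_base(self, js):
        """Effective length per unit multiplier (duration x Brownian rate)."""
        if self.cfg.clock == "mixed":
            er = np.exp(self.x)
            return self.dt[js] * 0.5 * (er[self._par[js]] + er[js])
        return self.dt[js].copy()

    def _set_logR(self, js, logRnew) -> None:
        if np.size(js) == 0:
            return
        self.logR[js] = logRnew
        self.Rm[js] = np.exp(logRnew)
        self._recompute_rho(np.asarray(js))

    def move_x_root(self) -> None:
        if not self._use_bm:
            return
        x0 = self.x[0]
        xprop = x0 + self.rng.uniform(-self._delta["x0"], self._delta["x0"])
        lo, hi = X0_RANGE
        if lo <= xprop <= hi:
            kids = self._kids[0]
            jmat = kids[None, :]
            mask = np.ones((1, 2), dtype=bool)
            dt = self.dt[jmat]
            Rfac = self.Rm[jmat] if self.cfg.clock == "mixed" else 1.0
            xk = self.x[kids][None, :]

            def term(xr):
                rates = 0.5 * (np.exp(xr) + np.exp(xk))
                out = self._aug_term(jmat, dt * rates * Rfac) \
                    + self._bm_edge_term(jmat, dt, (xk - xr) ** 2)
                return float(np.where(mask, out, 0.0).sum())

            logr = term(xprop) - term(x0)
            if self.cfg.likelihood == "pruning":
                rates_new = 0.5 * (np.exp(xprop) + np.exp(xk))
                logr += self._pruning_extra(kids, (dt * rates_new * Rfac)[0])
            acc = bool(self._metropolis_mask(logr))
        else:
            acc = False
        if acc:
            self.x[0] = xprop
            self._recompute_rho(self._kids[0].copy())
        self._tally("x0", acc, 1)

    def move_R_all(self) -> None:
        if not self._use_wn:
            return
        J = self.tree.branches
        u = self.rng.uniform(-self._delta["R"], self._delta["R"], J.size)
        logRnew = self.logR[J] + u
        dt = self.dt[J]
        base = self._ell_base(J)
        ell_new = base * np.exp(logRnew)
        delta = (self._aug_term(J, ell_new) - self._aug_term(J, self.ell[J])
                 + self._wn_edge_term(J, dt, logRnew)
                 - self._wn_edge_term(J, dt, self.logR[J]) + u)
        if self.cfg.likelihood == "pruning":
            # sequential per-branch updates under the exact likelihood
            acc = np.zeros(J.size, dtype=bool)
            for i, j in enumerate(J):
                d = float(delta[i]) + self._pruning_extra(
                    np.array([j]), np.array([ell_new[i]]))
                if bool(self._metropolis_mask(d)):
                    acc[i] = True
                    self._set_logR(np.array([j]), logRnew[i:i + 1])
            self._tally("R", acc.sum(), J.size)
            return
        acc = self._metropolis_mask(delta)
        self._set_logR(J[acc], logRnew[acc])
        self._tally("R", acc.sum(), J.size)

    def move_xr_swap_block(self, V) -> None:
        """Per-node pattern transfer between the clock components.

        Shifts the log-rate at node v and rescales the white-noise
        multipliers of the incident branches so that every effective length
        is exactly unchanged; the likelihood cancels and acceptance involves
        only the clock priors and the Jacobian prod_j r_j / r'_j of the
        rescaled multipliers.  This lets the sampler trade rate *patterns*
        (not just overall scale) between the Brownian and white-noise
        components, which the global compensatory move cannot do.
        """
        if self.cfg.clock != "mixed" or V.size == 0:
            return
        xs = self.x
        xv = xs[V]
        m = self.rng.uniform(-self._delta["xswap"], self._delta["xswap"], V.size)
        xprop = xv + m
        jmat, mask = self._jmat_for_nodes(V)
        dt = self.dt[jmat]
        xpar = xs[self._par[jmat]]
        xdn = xs[jmat]
        own = jmat == V[:, None]
        par_is_v = self._par[jmat] == V[:, None]
        xdn_new = np.where(own, xprop[:, None], xdn)
        xpar_new = np.where(par_is_v, xprop[:, None], xpar)
        r_old = 0.5 * (np.exp(xpar) + np.exp(xdn))
        r_new = 0.5 * (np.exp(xpar_new) + np.exp(xdn_new))
        log_ratio = np.where(mask, np.log(r_old) - np.log(r_new), 0.0)
        logR_old = self.logR[jmat]
        logR_new = logR_old + log_ratio
        before = np.where(mask, self._bm_edge_term(jmat, dt, (xdn - xpar) ** 2)
                          + self._wn_edge_term(jmat, dt, logR_old), 0.0).sum(axis=1)
        after = np.where(mask, self._bm_edge_term(jmat, dt, (xdn_new - xpar_new) ** 2)
                         + self._wn_edge_term(jmat, dt, logR_new), 0.0).sum(axis=1)
        logr = after - before + log_ratio.sum(axis=1)
        acc = self._metropolis_mask(logr)
        if np.any(acc):
            xs[V[acc]] = xprop[acc]
            js = jmat[acc][mask[acc]]
            self._set_logR(js, logR_new[acc][mask[acc]])
        self._tally("xswap", acc.sum(), V.size)

    def move_wn_scale(self) -> None:
        """Joint rescaling (mu_W, sigma2_W, R) -> (c mu_W, c^2 sigma2_W, c R).

        The gamma shape is invariant and the rate scales by 1/c, so the
        white-noise prior terms cancel against the Jacobian; acceptance
        involves only the exponential hyperpriors and the likelihood of the
        rescaled lengths.  Pure white-noise mode only (mixed pins mu_W = 1).
        """
        if self.cfg.clock != "wn":
            return
        u = self.rng.uniform(-self._delta["wnscale"], self._delta["wnscale"])
        c = np.exp(u)
        J = self.tree.branches
        ell_new = self.ell[J] * c
        if self.cfg.likelihood == "pruning":
            ell_full = self.ell.copy()
            ell_full[J] = ell_new
            delta = (pruning_loglik(self.tree, ell_full, self.aln, self.Q)
                     - self._pruning_cached())
        else:
            delta = float(np.sum(self._aug_term(J, ell_new)
                                 - self._aug_term(J, self.ell[J])))
        cfg = self.cfg
        delta += -(c - 1.0) * self.mu_w / cfg.prior_muw_mean
        delta += -(c * c - 1.0) * self.sigma2_w / cfg.prior_sigma2w_mean
        delta += 3.0 * u  # Jacobian of (mu, sigma2, R...) minus gamma terms
        acc = bool(self._metropolis_mask(delta))
        if acc:
            self.mu_w *= c
            self.sigma2_w *= c * c
            self._set_logR(J, self.logR[J] + u)
        self._tally("wnscale", acc, 1)

    def move_bscale(self) -> None:
        """Joint rescaling of sigma2_b and all x deviations from the root.

        With sigma2' = sigma2 e^u and every increment scaled by e^{u/2}, the
        Brownian prior terms and the Jacobian cancel exactly against the
        Jeffreys prior, leaving only the likelihood ratio (and truncation);
        this decorrelates the otherwise sticky (sigma_b, x) pair.
        """
        if not self._use_bm:
            return
        u = self.rng.uniform(-self._delta["bscale"], self._delta["bscale"])
        s2_new = self.sigma2_b * np.exp(u)
        lo, hi = SIGMA_B_RANGE
        if not lo * lo <= s2_new <= hi * hi:
            self._tally("bscale", False, 1)
            return
        x_new = self.x[0] + (self.x - self.x[0]) * np.exp(0.5 * u)
        J = self.tree.branches
        er = np.exp(x_new)
        rho_new = 0.5 * (er[self._par[J]] + er[J])
        if self.cfg.clock == "mixed":
            rho_new = rho_new * self.Rm[J]
        ell_new = self.dt[J] * rho_new
        if self.cfg.likelihood == "pruning":
            ell_full = self.ell.copy()
            ell_full[J] = ell_new
            delta = (pruning_loglik(self.tree, ell_full, self.aln, self.Q)
                     - self._pruning_cached())
        else:
            delta = float(np.sum(self._aug_term(J, ell_new)
                                 - self._aug_term(J, self.ell[J])))
        acc = bool(self._metropolis_mask(delta))
        if acc:
            self.sigma2_b = float(s2_new)
            self.x = x_new
            self._recompute_rho(J)
        self._tally("bscale", acc, 1)

    def compensatory_bm_wn_move(self) -> bool:
        """Shift all node log-rates by m and divide all multipliers by e^m.

        Every effective length is exactly unchanged, so the likelihood
        cancels; the acceptance ratio is the prior ratio times the Jacobian
        q^{-(2P-2)} of the 2P-2 divided multipliers (q = e^m).
        """
        if self.cfg.clock != "mixed":
            return False
        m = self.rng.uniform(-self._delta["comp"], self._delta["comp"])
        q = np.exp(m)
        lo, hi = X0_RANGE
        nb = self.tree.n_branches
        if lo <= self.x[0] + m <= hi:
            J = self.tree.branches
            dt = self.dt[J]
            delta = float(np.sum(self._wn_edge_term(J, dt, self.logR[J] - m)
                                 - self._wn_edge_term(J, dt, self.logR[J])))
            delta += -nb * m  # log |Jacobian| = log q^{-(2P-2)}
            acc = bool(self._metropolis_mask(delta))
        else:
            acc = False
        if acc:
            self.x += m
            self._set_logR(self.tree.branches, self.logR[1:] - m)
        self._tally("comp", acc, 1)
        return acc

    def move_x0_translate(self) -> None:
        """Independence redraw of the root log-rate, translating all x.

        Brownian increments are untouched, so the clock prior cancels and
        the acceptance ratio is the likelihood ratio under uniformly
        rescaled effective lengths.
        """
        if not self._use_bm:
            return
        lo, hi = X0_RANGE
        m = self.rng.uniform(lo, hi) - self.x[0]
        J = self.tree.branches
        ell_new = self.ell[J] * np.exp(m)
        delta = float(np.sum(self._aug_term(J, ell_new)
                             - self._aug_term(J, self.ell[J])))
        if self.cfg.likelihood == "pruning":
            before = pruning_loglik(self.tree, self.ell, self.aln, self.Q)
            ell_full = self.ell.copy()
            ell_full[1:] *= np.exp(m)
            delta = pruning_loglik(self.tree, ell_full, self.aln, self.Q) - before
        acc = bool(self._metropolis_mask(delta))
        if acc:
            self.x += m
            self._recompute_rho(J)
        self._tally("x0t", acc, 1)

    def move_x_redraw(self) -> None:
        """Propose a fresh Brownian history below the root from the prior.

        The proposal density equals the clock prior, which cancels, leaving
        the likelihood ratio; always accepted in prior-only runs.
        """
        if not self._use_bm:
            return
        xprop = self.x.copy()
        sd = np.sqrt(self.sigma2_b * self.dt[1:])
        eps = self.rng.normal(size=self.tree.n_branches)
        for v in range(1, self.tree.n_nodes):
            xprop[v] = xprop[self._par[v]] + sd[v - 1] * eps[v - 1]
        er = np.exp(xprop)
        J = self.tree.branches
        rho_new = 0.5 * (er[self._par[J]] + er[J])
        if self.cfg.clock == "mixed":
            rho_new = rho_new * self.Rm[J]
        ell_new = self.dt[J] * rho_new
        if self.cfg.likelihood == "pruning":
            ell_full = self.ell.copy()
            ell_full[J] = ell_new
            delta = (pruning_loglik(self.tree, ell_full, self.aln, self.Q)
                     - pruning_loglik(self.tree, self.ell, self.aln, self.Q))
        else:
            delta = float(np.sum(self._aug_term(J, ell_new)
                                 - self._aug_term(J, self.ell[J])))
        acc = bool(self._metropolis_mask(delta))
        if acc:
            self.x = xprop
            self._recompute_rho(J)
        self._tally("xr", acc, 1)

    def move_R_redraw(self) -> None:
        """Per-branch independence proposals from the gamma prior.

        Branch multipliers are a priori independent, so each branch accepts
        on its own likelihood ratio.
        """
        if not self._use_wn:
            return
        J = self.tree.branches
        dt = self.dt[J]
        shape = self.mu_w**2 * dt / self.sigma2_w
        rate = self.mu_w * dt / self.sigma2_w
        # exact draw of log Gamma(shape, rate) without underflow at tiny
        # shapes: G = G1 * U^(1/a) with G1 ~ Gamma(a+1)  (Marsaglia-Tsang)
        g1 = self.rng.gamma(shape + 1.0, 1.0 / rate)
        logRnew = np.log(g1) + np.log(self.rng.random(J.size)) / shape
        base = self._ell_base(J)
        with np.errstate(over="ignore"):
            ell_new = base * np.exp(logRnew)
        delta = self._aug_term(J, ell_new) - self._aug_term(J, self.ell[J])
        if self.cfg.likelihood == "pruning":
            # sequential per-branch independence updates, exact likelihood
            acc = np.zeros(J.size, dtype=bool)
            for i, j in enumerate(J):
                d = self._pruning_extra(np.array([j]), np.array([ell_new[i]]))
                if bool(self._metropolis_mask(d)):
                    acc[i] = True
                    self._set_logR(np.array([j]), logRnew[i:i + 1])
            self._tally("Rr", acc.sum(), J.size)
            return
        else:
            acc = self._metropolis_mask(delta)
        self._set_logR(J[acc], logRnew[acc])
        self._tally("Rr", acc.sum(), J.size)

    def move_sigma2b_gibbs(self) -> None:
        """Exact Gibbs draw of the Brownian variance.

        sigma2_b enters only the normal increments, so its full conditional
        is inverse-gamma (shape nb/2, scale S/2 with S = sum diff^2/dt)
        truncated to the prior range, for any likelihood mode.
        """
        if not self._use_bm:
            return
        from scipy.special import gammainc, gammaincinv
        J = self.tree.branches
        S = float(np.sum((self.x[J] - self.x[self._par[J]]) ** 2 / self.dt[J]))
        if S <= 0:
            return
        a = 0.5 * J.size
        # inv-gamma CDF at x is the upper gamma CDF of (S/2)/x
        lo, hi = SIGMA_B_RANGE
        g_lo = gammainc(a, 0.5 * S / (hi * hi))   # CDF complement at upper bound
        g_hi = gammainc(a, 0.5 * S / (lo * lo))
        if g_hi - g_lo <= 0:
            return
        u = g_lo + self.rng.random() * (g_hi - g_lo)
        y = gammaincinv(a, u)
        if y > 0:
            self.sigma2_b = float(np.clip(0.5 * S / y, lo * lo, hi * hi))

    # ---- scalar hyperparameter moves ---------------------------------
    def _scale_move(self, name, get, setv, logprior_fn) -> None:
        cur = get()
        before = logprior_fn()
        u = self.rng.uniform(-self._delta[name], self._delta[name])
        setv(cur * np.exp(u))
        after = logprior_fn()
        acc = bool(self._metropolis_mask(after - before + u))
        if not acc:
            setv(cur)
        self._tally(name, acc, 1)

    def _bm_prior_full(self) -> float:
        lo, hi = SIGMA_B_RANGE
        if not lo * lo <= self.sigma2_b <= hi * hi:
            return -np.inf
        J = self.tree.branches
        xd2 = (self.x[J] - self.x[self._par[J]]) ** 2
        return float(np.sum(self._bm_edge_term(J, self.dt[J], xd2))
                     - np.log(self.sigma2_b))

    def _wn_prior_full(self) -> float:
        J = self.tree.branches
        lp = float(np.sum(self._wn_edge_term(J, self.dt[J], self.logR[J])))
        lp += -self.sigma2_w / self.cfg.prior_sigma2w_mean
        if self.cfg.clock == "wn":
            lp += -self.mu_w / self.cfg.prior_muw_mean
        return lp

    def move_hyper(self) -> None:
        if self._use_bm:
            self._scale_move("sigma2_b", lambda: self.sigma2_b,
                             lambda v: setattr(self, "sigma2_b", v),
                             self._bm_prior_full)
        if self._use_wn:
            self._scale_move("sigma2_w", lambda: self.sigma2_w,
                             lambda v: setattr(self, "sigma2_w", v),
                             self._wn_prior_full)
            if self.cfg.clock == "wn":
                def setmu(v):
                    self.mu_w = v
                self._scale_move("mu_w", lambda: self.mu_w, setmu,
                                 self._wn_prior_full)

    def move_bd(self) -> None:
        cfg = self.cfg
        if cfg.mode == "node":
            names = (("bd_d", "d", cfg.prior_d_mean), ("bd_b", "b", cfg.prior_b_mean))
        else:
            names = (("bd_d", "d", cfg.prior_d_mean), ("bd_mu", "mu", cfg.prior_mu_mean),
                     ("bd_psi", "psi", cfg.prior_psi_mean))
        if cfg.mode == "node":
            def lp():
                return (time_priors.node_bd_logdensity(self.tree, self.bd)
                        - self.bd.d / cfg.prior_d_mean - self.bd.b / cfg.prior_b_mean)
        else:
            def lp():
                return (time_priors.serial_bd_logdensity(
                            self.tree, self.bd, include_ntot=cfg.use_ntot)
                        - self.bd.d / cfg.prior_d_mean
                        - self.bd.mu / cfg.prior_mu_mean
                        - self.bd.psi / cfg.prior_psi_mean)
        for mv, attr, mean in names:
            if cfg.mode == "tip" and attr == "psi" and self._fossil_tips.size == 0 \
                    and self.bd.psi == 0.0:
                continue
            self._scale_move(mv, lambda a=attr: getattr(self.bd, a),
                             lambda v, a=attr: setattr(self.bd, a, v), lp)

    # ---- GTR moves ----------------------------------------------------
    def _gtr_loglik(self) -> float:
        if self.cfg.likelihood == "none":
            return 0.0
        if self.cfg.likelihood == "pruning":
            return pruning_loglik(self.tree, self.ell, self.aln, self.Q)
        off = ~np.eye(4, dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(self._ss_Nab[off] > 0,
                            self._ss_Nab[off] * np.log(self.Q.Q[off]), 0.0).sum()
        T = self.suff.dwell.T @ self.ell
        root_term = float(self.suff.root_counts @ np.log(self.Q.pi))
        return float(term + T @ np.diag(self.Q.Q)) + root_term

    def _dirichlet_move(self, name, vec_get, vec_set) -> None:
        cur = vec_get()
        conc = self._delta[name]
        alpha = conc * cur + 1e-3
        prop = self.rng.dirichlet(alpha)
        if np.any(prop <= 1e-10):
            self._tally(name, False, 1)
            return
        alpha_rev = conc * prop + 1e-3
        log_h = (_dirichlet_logpdf(cur, alpha_rev) - _dirichlet_logpdf(prop, alpha))
        before = self._gtr_loglik()
        old_gtr, old_Q = self.gtr, self.Q
        try:
            vec_set(prop)
        except ValueError:
            self.gtr, self.Q = old_gtr, old_Q
            self._tally(name, False, 1)
            return
        after = self._gtr_loglik()
        acc = bool(self._metropolis_mask(after - before + log_h))
        if acc:
            self._plik = None
            if self.cfg.likelihood == "augmented":
                self._ss_ntot, self._ss_nlogq, self._ss_wq = \
                    self.suff.branch_terms(self.Q)
        else:
            self.gtr, self.Q = old_gtr, old_Q
        self._tally(name, acc, 1)

    def move_gtr(self) -> None:
        if self.cfg.likelihood == "none":
            return

        def set_rho(v):
            self.gtr = GTRParams(v, self.gtr.pi)
            self.Q = build_gtr(self.gtr)

        def set_pi(v):
            self.gtr = GTRParams(self.gtr.rho, v)
            self.Q = build_gtr(self.gtr)

        self._dirichlet_move("rho_c", lambda: self.gtr.rho, set_rho)
        self._dirichlet_move("pi_c", lambda: self.gtr.pi, set_pi)

    # ------------------------------------------------------------------
    # main loop
    # ------------------------------------------------------------------
    def sweep(self) -> None:
        """One light sweep over the mobile parameters."""
        for p in (0, 1):
            self.move_ages_block(self._age_blocks[p])
            self.move_ages_uniform_block(self._age_blocks[p])
        self.move_root_age()
        if self.cfg.mode == "tip":
            self.move_fossil_ages()
        if self._use_bm:
            for p in (0, 1):
                self.move_x_block(self._x_blocks[p])
            self.move_x_root()
            self.move_sigma2b_gibbs()
        if self._use_wn:
            self.move_R_all()
            self.move_wn_scale()
        if self.cfg.clock == "mixed":
            for p in (0, 1):
                self.move_xr_swap_block(self._x_blocks[p])
        self.compensatory_bm_wn_move()
        self.move_hyper()

    def cycle_extras(self) -> None:
        """Global/independence moves and fast-mixing blocks, once per cycle."""
        self.move_tree_scale()
        if self._use_bm:
            self.move_x0_translate()
            self.move_x_redraw()
            self.move_bscale()
        if self._use_wn:
            self.move_R_redraw()
        self.move_bd()
        self.move_gtr()

    def run(self, n_cycles: int | None = None) -> ChainResult:
        cfg = self.cfg
        n_cycles = cfg.n_cycles if n_cycles is None else n_cycles
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            self._run(n_cycles)
        return self.result()

    def _run(self, n_cycles: int) -> None:
        cfg = self.cfg
        for _ in range(n_cycles):
            if cfg.likelihood == "augmented" and self.cycle % cfg.refresh_every == 0:
                self.gibbs_refresh_mapping()
            if self.cfg.likelihood == "pruning":
                # sequential per-node processing keeps acceptance high at tiny P
                for p in (0, 1):
                    for v in self._age_blocks[p]:
                        self.move_ages_block(np.array([v]))
                        self.move_ages_uniform_block(np.array([v]))
                    for v in self._x_blocks[p]:
                        if self._use_bm:
                            self.move_x_block(np.array([v]))
                self.move_root_age()
                self.move_tree_scale()
                if cfg.mode == "tip":
                    self.move_fossil_ages()
                if self._use_bm:
                    self.move_x_root()
                    self.move_x0_translate()
                    self.move_x_redraw()
                    self.move_sigma2b_gibbs()
                    self.move_bscale()
                if self._use_wn:
                    self.move_R_all()
                    self.move_R_redraw()
                    self.move_wn_scale()
                if self.cfg.clock == "mixed":
                    for p in (0, 1):
                        self.move_xr_swap_block(self._x_blocks[p])
                self.compensatory_bm_wn_move()
                self.move_hyper()
                self.move_bd()
                self.move_gtr()
            else:
                for _ in range(cfg.sweeps_per_cycle):
                    self.sweep()
                self.cycle_extras()
            self.cycle += 1
            if self._adapting and self.cycle <= cfg.burnin:
                if self.cycle % 50 == 0:
                    self._adapt()
                if self.cycle == cfg.burnin:
                    self._adapting = False
            if self.cycle > cfg.burnin and (self.cycle - cfg.burnin) % cfg.thin == 0:
                self._record()

    def _record(self) -> None:
        rec = {
            "cycle": self.cycle,
            "logprior": self.logprior(),
            "loglik": self.loglik(),
            "treelen": float(self.ell[1:].sum()),
            "root_age": self.tree.root_age,
            "sigma2_b": self.sigma2_b if self._use_bm else np.nan,
            "sigma2_w": self.sigma2_w if self._use_wn else np.nan,
            "mu_w": self.mu_w if self.cfg.clock == "wn" else
                    (1.0 if self.cfg.clock == "mixed" else np.nan),
            "x0": self.x[0] if self._use_bm else np.nan,
        }
        if self.cfg.mode == "node":
            rec["bd_d"], rec["bd_b"] = self.bd.d, self.bd.b
        else:
            rec["bd_d"], rec["bd_mu"], rec["bd_psi"] = \
                self.bd.d, self.bd.mu, self.bd.psi
        if self.cfg.clock == "mixed":
            log_rb = np.logaddexp(self.x[self._par[1:]], self.x[1:]) - np.log(2.0)
            v_b = float(np.var(log_rb, ddof=1))
            v_w = float(np.var(self.logR[1:], ddof=1))
            rec["f_w"] = np.nan if v_b + v_w == 0 else v_w / (v_b + v_w)
        if not np.isfinite(rec["logprior"]) or not np.isfinite(rec["loglik"]):
            raise RuntimeError(f"non-finite posterior at cycle {self.cycle}: {rec}")
        self._records.append(rec)
        self._ages_out.append(self.tree.ages.copy())
        if self._use_bm:
            self._x_out.append(self.x.copy())
        if self._use_wn:
            self._r_out.append(self.Rm.copy())

    def result(self) -> ChainResult:
        trace = pd.DataFrame(self._records)
        return ChainResult(
            trace=trace, config=self.cfg,
            age_samples=np.array(self._ages_out) if self._ages_out else
            np.zeros((0, self.tree.n_nodes)),
            x_samples=np.array(self._x_out) if self._x_out else None,
            r_samples=np.array(self._r_out) if self._r_out else None,
            sampler=self)


def _dirichlet_logpdf(x, alpha) -> float:
    return float(np.sum((alpha - 1) * np.log(x)) + gammaln(alpha.sum())
                 - np.sum(gammaln(alpha)))


def run_chain(tree: TimeTree, aln: Alignment | None, config: RunConfig,
              calibrations=None, fossil_intervals=None,
              rng: np.random.Generator | None = None,
              gtr: GTRParams | None = None) -> ChainResult:
    """Run one MCMC chain and return its trace and posterior samples."""
    sampler = MixedClockSampler(tree, aln, config, calibrations=calibrations,
                                fossil_intervals=fossil_intervals, rng=rng, gtr=gtr)
    return sampler.run()


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------
def ess(series) -> float:
    """Effective sample size from the autocorrelation time.

    Uses Geyer's initial positive-sequence truncation: lag-autocorrelations
    are summed in adjacent pairs until a pair sum turns negative.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    rho = acov / acov[0]
    tau = 1.0
    for m in range(1, n // 2):
        pair = rho[2 * m - 1] + rho[2 * m]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / max(tau, 1e-12)))


def tracecomp(traces, burnin: int = 0) -> pd.DataFrame:
    """Per-statistic ESS and between-chain relative discrepancy.

    Discrepancy is ``|mean_1 - mean_2| / pooled SD`` for the first two
    traces, mirroring the tracecomp convergence report (ESS above ~100 and
    discrepancy below ~0.1 indicate adequate runs).
    """
    if len(traces) < 2:
        raise ValueError("tracecomp needs at least two traces")
    dfs = []
    for t in traces:
        df = t.trace if hasattr(t, "trace") else t
        if len(df) <= burnin:
            raise ValueError("trace shorter than burn-in")
        dfs.append(df.iloc[burnin:])
    cols = [c for c in dfs[0].columns
            if c != "cycle" and all(c in d.columns for d in dfs)
            and np.issubdtype(dfs[0][c].dtype, np.number)]
    out = {}
    for c in cols:
        vals = [d[c].to_numpy(dtype=float) for d in dfs]
        if any(np.all(~np.isfinite(v)) for v in vals):
            continue
        esses = [ess(v) for v in vals]
        m1, m2 = np.nanmean(vals[0]), np.nanmean(vals[1])
        pooled = np.sqrt(0.5 * (np.nanvar(vals[0]) + np.nanvar(vals[1])))
        disc = 0.0 if pooled == 0 else abs(m1 - m2) / pooled
        out[c] = {"discrepancy": disc,
                  **{f"ess{i+1}": e for i, e in enumerate(esses)}}
    return pd.DataFrame(out).T
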