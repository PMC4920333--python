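"""Forward simulators and the clock-recovery experiment designs.

Everything the validation suite needs is generated here: serially sampled
birth-death trees with diversified extant sampling, Yule trees, branch-rate
histories under each relaxed clock, GTR alignments, and the re-analysis
loop that simulates data under a known clock, re-fits the mixed clock by
MCMC and scores how much of the log-rate variance is attributed to each
component.

Study conditions (tree sizes, rates, noise levels) are fixed once as module
defaults of a scale comparable to a fast-evolving nuclear gene across
placental mammals: ~30-taxon trees with a ~100 Myr root, a mean substitution
rate of 0.01 /site/Myr, SD of log branch rates around 0.5, white-noise
stationary variance 0.2, and 1000-site alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clocks
from .clocks import BrownianState, MixedState, WhiteNoiseState, effective_lengths
from .engine import RunConfig, ess, run_chain
from .gtr import GTRParams, build_gtr, simulate_sequences
from .io import Alignment
from .time_priors import SerialBDParams, sample_node_ages
from .timetree import TimeTree

__all__ = ["SimReplicate", "simulate_serial_bd_tree", "simulate_yule_tree",
           "simulate_clock", "clock_recovery_experiment", "DESIGNS",
           "default_gtr", "node_matched_tree"]

# near-uniform GTR used for all simulation studies (transition-rich, AT-rich)
DEFAULT_RHO = np.array([0.12, 0.28, 0.10, 0.10, 0.30, 0.10])
DEFAULT_PI = np.array([0.30, 0.20, 0.20, 0.30])

DESIGNS = ("node_matched", "tip_matched_prior", "tip_yule_misspec",
           "tip_posterior_like")

#: default simulation scale (see module docstring)
N_TAXA = 30
ROOT_AGE = 100.0
YULE_RATE = 0.02
N_SITES = 1000
X0_TRUE = float(np.log(0.01))
SIGMA2_B_TRUE = 0.005
SIGMA2_W_TRUE = 0.2
TIP_BD = dict(d=0.05, mu=0.10, psi=0.02, t_c=25.0)
CALIB_FRACTION = 0.6
CALIB_HALFWIDTH = 0.15          # relative half-width of hard bounds
FOSSIL_INTERVAL_HW = 2.5        # Myr half-width on fossil tip ages


def default_gtr() -> GTRParams:
    return GTRParams(DEFAULT_RHO / DEFAULT_RHO.sum(), DEFAULT_PI / DEFAULT_PI.sum())


@dataclass
class SimReplicate:
    """One simulated dataset plus its generating truth and provenance."""

    tree: TimeTree
    clock_state: object
    lengths: np.ndarray
    aln: Alignment | None
    true_f_w: float | None
    provenance: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# tree simulators
# ----------------------------------------------------------------------
class _Node:
    __slots__ = ("age", "children", "kind")

    def __init__(self, age, kind="internal"):
        self.age = age
        self.children = []
        self.kind = kind  # internal | extant | fossil | dead


def _grow(start_age: float, p: SerialBDParams, rng, budget: list) -> _Node | None:
    """Simulate one lineage from start_age; return sampled subtree or None."""
    total = p.lam + p.mu + p.psi
    stack = [(start_age, None, None)]  # (age, parent_node, slot)
    root_holder = [None]
    while stack:
        age, parent, slot = stack.pop()
        budget[0] -= 1
        if budget[0] < 0:
            raise _TooLarge
        t_next = age - rng.exponential(1.0 / total) if total > 0 else -np.inf
        if t_next <= p.t_c:
            node = _Node(0.0, "extant")
        else:
            u = rng.random() * total
            if u < p.lam:
                node = _Node(t_next, "internal")
                stack.append((t_next, node, 0))
                stack.append((t_next, node, 1))
            elif u < p.lam + p.mu:
                node = _Node(t_next, "dead")
            else:
                node = _Node(t_next, "fossil")
        if parent is None:
            root_holder[0] = node
        else:
            parent.children.append(node)
    return _prune(root_holder[0])


class _TooLarge(Exception):
    pass


def _prune(node: _Node) -> _Node | None:
    """Drop unsampled lineages; collapse single-child chains."""
    if node.kind in ("extant", "fossil"):
        return node
    if node.kind == "dead":
        return None
    kept = [c for c in (_prune(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    return node


def _to_timetree(root_age: float, left: _Node, right: _Node) -> TimeTree:
    root = _Node(root_age, "internal")
    root.children = [left, right]
    order: list[_Node] = []

    def walk(nd):
        order.append(nd)
        for c in nd.children:
            walk(c)

    walk(root)
    index = {id(nd): i for i, nd in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.int64)
    children = np.full((n, 2), -1, dtype=np.int64)
    ages = np.zeros(n)
    fossil = np.zeros(n, dtype=bool)
    labels: dict[int, str] = {}
    n_ext = n_fos = 0
    for nd in order:
        i = index[id(nd)]
        ages[i] = nd.age
        for k, c in enumerate(nd.children):
            j = index[id(c)]
            parent[j] = i
            children[i, k] = j
        if not nd.children:
            if nd.kind == "fossil":
                n_fos += 1
                labels[i] = f"fossil{n_fos}"
                fossil[i] = True
            else:
                n_ext += 1
                labels[i] = f"taxon{n_ext}"
    return TimeTree(parent, children, ages, labels, fossil)


def simulate_serial_bd_tree(params: SerialBDParams, rng: np.random.Generator,
                            root_age: float | None = None,
                            root_age_mean: float = 100.0,
                            extant_range=(2, 10_000), fossil_range=(0, 10_000),
                            max_tries: int = 10_000):
    """Forward-simulate a sampled tree under the serial BD process.

    Two lineages start at the root age (drawn from its exponential prior
    when not given); speciation, extinction and fossil-sampling events occur
    until the cut-off; fossil sampling terminates the lineage and creates a
    dated tip; every lineage alive at the cut-off yields exactly one extant
    tip.  Trees in which either root child leaves no sampled descendant are
    rejected and redrawn, as are trees outside the requested tip-count
    ranges.  Returns ``(tree, info)`` where info records the draw of the
    unobserved post-cut-off diversity N_tot.
    """
    for _ in range(max_tries):
        ra = root_age if root_age is not None \
            else params.t_c + rng.exponential(root_age_mean)
        if ra <= params.t_c:
            continue
        budget = [200_000]
        try:
            left = _grow(ra, params, rng, budget)
            right = _grow(ra, params, rng, budget)
        except _TooLarge:
            continue
        if left is None or right is None:
            continue
        tree = _to_timetree(ra, left, right)
        n_ext = int(np.sum(tree.is_tip & ~tree.fossil))
        n_fos = int(np.sum(tree.fossil))
        if not (extant_range[0] <= n_ext <= extant_range[1]
                and fossil_range[0] <= n_fos <= fossil_range[1]):
            continue
        # unobserved diversity: each cut-off lineage grows as a pure birth
        p_geo = np.exp(-params.lam * params.t_c)
        n_tot = n_ext + int(rng.negative_binomial(n_ext, p_geo))
        return tree, {"n_extant": n_ext, "n_fossil": n_fos, "n_tot": n_tot,
                      "root_age": float(ra)}
    raise RuntimeError("serial-BD simulation failed to satisfy the constraints; "
                       "parameter regime may have vanishing survival")


def simulate_yule_tree(lam: float, root_age: float, n_tips: int,
                       rng: np.random.Generator) -> TimeTree:
    """Ultrametric Yule tree conditioned on root age and tip count.

    Non-root node ages are i.i.d. truncated exponentials; the ranked
    topology is built by splitting a uniformly chosen extant lineage at each
    successive speciation time.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    inner_ages = np.sort(sample_node_ages(n_tips - 2, root_age, lam, lam, rng))[::-1]
    root = _Node(root_age)
    open_slots = [_Node(0.0, "extant"), _Node(0.0, "extant")]
    root.children = list(open_slots)
    for a in inner_ages:
        k = rng.integers(len(open_slots))
        nd = open_slots[k]
        nd.age, nd.kind = a, "internal"
        nd.children = [_Node(0.0, "extant"), _Node(0.0, "extant")]
        open_slots[k] = nd.children[0]
        open_slots.append(nd.children[1])
    return _to_timetree(root_age, root.children[0], root.children[1])


# ----------------------------------------------------------------------
# clock simulators
# ----------------------------------------------------------------------
def simulate_clock(kind: str, tree: TimeTree, rng: np.random.Generator,
                   sigma2_b: float = SIGMA2_B_TRUE, x0: float = X0_TRUE,
                   sigma2_w: float = SIGMA2_W_TRUE, mu_w: float = 1.0):
    """Forward-simulate a branch-rate history; returns (state, lengths, f_w)."""
    dt = tree.durations()
    bm = wn = None
    if kind in ("bm", "mixed"):
        x = np.zeros(tree.n_nodes)
        x[0] = x0
        sd = np.sqrt(sigma2_b * dt)
        eps = rng.normal(size=tree.n_branches)
        for v in range(1, tree.n_nodes):
            x[v] = x[tree.parent[v]] + sd[v - 1] * eps[v - 1]
        bm = BrownianState(x, sigma2_b)
    if kind in ("wn", "mixed"):
        muw = 1.0 if kind == "mixed" else mu_w
        shape = muw * muw * dt / sigma2_w
        scale = sigma2_w / (muw * dt)
        R = np.ones(tree.n_nodes)
        # floor guards float underflow of tiny-shape gamma draws
        R[1:] = np.maximum(rng.gamma(shape, scale), 1e-290)
        wn = WhiteNoiseState(R, muw, sigma2_w)
    if kind == "bm":
        state = bm
        f_w = 0.0
    elif kind == "wn":
        state = wn
        f_w = 1.0
    elif kind == "mixed":
        state = MixedState(bm, wn)
        f_w = clocks.variance_partition(state, tree).f_w
    else:
        raise ValueError(f"unknown clock kind {kind!r}")
    return state, effective_lengths(state, tree), f_w


# ----------------------------------------------------------------------
# experiment designs
# ----------------------------------------------------------------------
def node_matched_tree(seed: int = 999):
    """The fixed calibrated design tree: Yule topology with hard bounds on
    ~60% of internal nodes (root included), windows +/-15% of the true age."""
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(YULE_RATE, ROOT_AGE, N_TAXA, rng)
    internal = tree.internal
    k = max(1, int(round(CALIB_FRACTION * internal.size)))
    chosen = set(rng.choice(internal[1:], size=k - 1, replace=False).tolist())
    chosen.add(0)
    bounds = {int(v): ((1 - CALIB_HALFWIDTH) * tree.ages[v],
                       (1 + CALIB_HALFWIDTH) * tree.ages[v]) for v in chosen}
    return tree, bounds


def _mixed_hyperparams(tree: TimeTree, f_target: float, v_total: float = 0.25):
    """Split a target total log-rate variance between the two components."""
    dt = tree.durations()
    mid_depth = tree.ages[0] - 0.5 * (tree.ages[tree.parent[1:]] + tree.ages[1:])
    s2b = max((1.0 - f_target) * v_total / float(np.mean(mid_depth)), 1e-6)
    s2w = max(f_target * v_total / float(np.mean(1.0 / dt)), 1e-6)
    return s2b, s2w


def _simulate_replicate(design: str, sim_clock: str, rng, n_sites: int,
                        f_target: float | None = None) -> SimReplicate:
    gtr = default_gtr()
    Q = build_gtr(gtr)
    prov: dict = {"design": design, "sim_clock": sim_clock}
    if design in ("node_matched", "tip_posterior_like"):
        tree, bounds = node_matched_tree()
        prov["calibrations"] = bounds
    elif design == "tip_matched_prior":
        params = SerialBDParams(**TIP_BD)
        tree, info = simulate_serial_bd_tree(
            params, rng, root_age=None, root_age_mean=100.0,
            extant_range=(25, 45), fossil_range=(2, 20))
        prov.update(info)
        prov["fossil_intervals"] = {
            tree.labels[v]: (max(params.t_c + 0.1,
                                 tree.ages[v] - FOSSIL_INTERVAL_HW),
                             tree.ages[v] + FOSSIL_INTERVAL_HW)
            for v in np.flatnonzero(tree.fossil)}
    elif design == "tip_yule_misspec":
        tree = simulate_yule_tree(YULE_RATE, ROOT_AGE, N_TAXA, rng)
    else:
        raise ValueError(f"unknown design {design!r}")

    kw = {}
    if sim_clock == "mixed":
        f_target = 0.5 if f_target is None else f_target
        s2b, s2w = _mixed_hyperparams(tree, f_target)
        kw = dict(sigma2_b=s2b, sigma2_w=s2w)
    state, lengths, f_w = simulate_clock(sim_clock, tree, rng, **kw)
    aln = simulate_sequences(tree, lengths, Q, n_sites, rng)
    prov["n_sites"] = n_sites
    return SimReplicate(tree, state, lengths, aln, f_w, prov)


def _analysis_config(design: str, rep: SimReplicate, n_cycles: int, burnin: int,
                     sweeps: int, seed: int) -> tuple[RunConfig, dict, dict]:
    mode = "node" if design == "node_matched" else "tip"
    cfg = RunConfig(clock="mixed", mode=mode, n_cycles=n_cycles, burnin=burnin,
                    sweeps_per_cycle=sweeps, seed=seed)
    calib = rep.provenance.get("calibrations")
    fossils = rep.provenance.get("fossil_intervals")
    if mode == "tip" and "n_tot" in rep.provenance:
        cfg.ntot = int(rep.provenance["n_tot"])
    return cfg, calib or {}, fossils or {}


def clock_recovery_experiment(design: str, sim_clock: str,
                              n_replicates: int = 3, seed: int = 1,
                              n_sites: int = N_SITES,
                              n_cycles: int = 1200, burnin: int = 450,
                              sweeps_per_cycle: int = 5, refresh_every: int = 2,
                              mixed_f_targets=(0.25, 0.5, 0.75),
                              min_ess: float = 10.0) -> pd.DataFrame:
    """Simulate under a known clock, re-analyse under the mixed clock.

    For each replicate the posterior-mean white-noise variance fraction
    ``f_W`` is recorded next to its true value (0 for a pure Brownian
    simulation, 1 for pure white noise).  A replicate whose f_W effective
    sample size falls below ``min_ess`` is rerun once with a fresh seed and
    flagged as failed if still unconverged.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    rows = []
    root_ss = np.random.SeedSequence(seed)
    for i, child in enumerate(root_ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        ft = mixed_f_targets[i % len(mixed_f_targets)] if sim_clock == "mixed" else None
        rep = _simulate_replicate(design, sim_clock, rng, n_sites, f_target=ft)
        est = None
        for attempt in range(2):
            run_seed = int(child.generate_state(1)[0] % (2**31)) + attempt
            cfg, calib, fossils = _analysis_config(design, rep, n_cycles, burnin,
                                                   sweeps_per_cycle, run_seed)
            cfg.refresh_every = refresh_every
            res = run_chain(rep.tree, rep.aln, cfg, calibrations=calib,
                            fossil_intervals=fossils)
            fw = res.trace["f_w"].to_numpy()
            fw_ess = ess(fw)
            est = float(np.mean(fw))
            if fw_ess >= min_ess:
                break
        rows.append({"replicate": i, "design": design, "sim_clock": sim_clock,
                     "true_f_w": rep.true_f_w, "est_f_w": est,
                     "ess_f_w": fw_ess, "converged": fw_ess >= min_ess,
                     "n_taxa": rep.tree.n_tips, "n_sites": n_sites})
    return pd.DataFrame(rows)
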