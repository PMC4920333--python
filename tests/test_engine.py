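"""MCMC engine mechanics: moves, diagnostics, determinism."""

import numpy as np
import pandas as pd
import pytest

import mixclock as mc
from mixclock.engine import (MixedClockSampler, RunConfig, ess, run_chain,
                             tracecomp)
from mixclock.gtr import build_gtr, simulate_sequences
from mixclock.simulate import default_gtr, simulate_clock


def _small_setup(rng, n_sites=120):
    tree = mc.read_newick("((A:10,B:10):10,C:20);")
    Q = build_gtr(default_gtr())
    st, lengths, _ = simulate_clock("mixed", tree, rng, sigma2_b=0.01,
                                    x0=np.log(0.02), sigma2_w=0.2)
    aln = simulate_sequences(tree, lengths, Q, n_sites, rng)
    return tree, aln


class TestDeterminism:
    def test_same_seed_identical_trace(self, rng):
        tree, aln = _small_setup(rng)
        cfg = RunConfig(clock="mixed", mode="node", n_cycles=60, burnin=10,
                        sweeps_per_cycle=2, seed=42)
        r1 = run_chain(tree, aln, cfg, calibrations={0: (15.0, 25.0)})
        r2 = run_chain(tree, aln, cfg, calibrations={0: (15.0, 25.0)})
        pd.testing.assert_frame_equal(r1.trace, r2.trace)

    def test_checkpoint_resume_matches_single_run(self, rng):
        tree, aln = _small_setup(rng)
        cfg = RunConfig(clock="mixed", mode="node", n_cycles=60, burnin=10,
                        sweeps_per_cycle=2, seed=7)
        full = MixedClockSampler(tree, aln, cfg, calibrations={0: (15.0, 25.0)})
        full.run(60)
        split = MixedClockSampler(tree, aln, cfg, calibrations={0: (15.0, 25.0)})
        split.run(25)
        split.run(35)  # resume from internal state: same rng stream
        pd.testing.assert_frame_equal(full.result().trace, split.result().trace)


class TestCompensatoryMove:
    def test_effective_lengths_exactly_unchanged(self, rng):
        tree, aln = _small_setup(rng)
        cfg = RunConfig(clock="mixed", mode="node", n_cycles=5, burnin=0,
                        sweeps_per_cycle=1, seed=1)
        s = MixedClockSampler(tree, aln, cfg, calibrations={0: (15.0, 25.0)})
        for _ in range(200):
            before = s.ell.copy()
            s.compensatory_bm_wn_move()
            assert np.max(np.abs(s.ell - before)) <= 1e-12 * max(before.max(), 1)

    def test_zero_shift_is_identity(self, rng):
        tree, aln = _small_setup(rng)
        cfg = RunConfig(clock="mixed", mode="node", n_cycles=1, burnin=0,
                        sweeps_per_cycle=1, seed=1)
        s = MixedClockSampler(tree, aln, cfg, calibrations={0: (15.0, 25.0)})
        s._delta["comp"] = 1e-300  # m ~ 0: prior ratio and Jacobian vanish
        x0, R0 = s.x.copy(), s.Rm.copy()
        s.compensatory_bm_wn_move()
        assert np.allclose(s.x, x0) and np.allclose(s.Rm, R0)
        assert s._acc["comp"][0] == 1  # always accepted

    def test_swap_move_preserves_lengths(self, rng):
        tree, aln = _small_setup(rng)
        cfg = RunConfig(clock="mixed", mode="node", n_cycles=5, burnin=0,
                        sweeps_per_cycle=1, seed=3)
        s = MixedClockSampler(tree, aln, cfg, calibrations={0: (15.0, 25.0)})
        for p in (0, 1):
            for _ in range(100):
                before = s.ell.copy()
                s.move_xr_swap_block(s._x_blocks[p])
                assert np.allclose(s.ell, before, rtol=1e-10)


class TestConstraints:
    def test_calibrations_never_violated(self, rng):
        tree, aln = _small_setup(rng)
        bounds = {0: (18.0, 22.0), 1: (8.0, 15.0)}
        cfg = RunConfig(clock="mixed", mode="node", n_cycles=150, burnin=20,
                        sweeps_per_cycle=2, seed=5)
        res = run_chain(tree, aln, cfg, calibrations=bounds)
        for v, (lo, hi) in bounds.items():
            ages = res.age_samples[:, v]
            assert np.all((ages >= lo) & (ages <= hi))

    def test_fossil_intervals_respected(self, rng):
        tree = mc.read_newick("((A:26,F:10):14,C:40);", fossil_tips={"F"})
        Q = build_gtr(default_gtr())
        lengths = np.zeros(tree.n_nodes)
        lengths[1:] = 0.01 * tree.durations()
        aln = simulate_sequences(tree, lengths, Q, 100, rng)
        cfg = RunConfig(clock="wn", mode="tip", tc=3.0, n_cycles=150, burnin=20,
                        sweeps_per_cycle=2, seed=5, use_ntot=False)
        res = run_chain(tree, aln, cfg, fossil_intervals={"F": (14.0, 22.0)})
        f = tree.tip_label_to_node["F"]
        ages = res.age_samples[:, f]
        assert np.all((ages >= 14.0) & (ages <= 22.0))
        assert ages.std() > 0  # the fossil age is actually sampled

    def test_nan_posterior_aborts(self, rng):
        tree, aln = _small_setup(rng)
        cfg = RunConfig(clock="mixed", mode="node", n_cycles=5, burnin=0,
                        sweeps_per_cycle=1, seed=5)
        s = MixedClockSampler(tree, aln, cfg, calibrations={0: (15.0, 25.0)})
        s.sigma2_b = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            s.run(3)


class TestGibbsRefresh:
    def test_refresh_leaves_parameters_unchanged(self, rng):
        tree, aln = _small_setup(rng)
        cfg = RunConfig(clock="mixed", mode="node", n_cycles=5, burnin=0,
                        sweeps_per_cycle=1, seed=5)
        s = MixedClockSampler(tree, aln, cfg, calibrations={0: (15.0, 25.0)})
        ell = s.ell.copy()
        ages = s.tree.ages.copy()
        s.gibbs_refresh_mapping()
        assert np.array_equal(s.ell, ell) and np.array_equal(s.tree.ages, ages)

    def test_zero_length_equal_endpoints_empty_history(self, jc_q, rng):
        tree = mc.read_newick("(A:1,B:1);")
        aln = mc.Alignment.from_strings(["A", "B"], ["ACGT", "ACGT"])
        S = mc.sample_mapping(tree, np.zeros(3), aln, jc_q, rng)
        assert S.events_per_branch().sum() == 0


class TestTracecomp:
    def test_iid_gaussian_ess(self, rng):
        n = 4000
        x = rng.normal(size=n)
        assert ess(x) == pytest.approx(n, rel=0.2)

    def test_ar1_ess_closed_form(self, rng):
        n, rho = 40_000, 0.8
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        assert ess(x) == pytest.approx(n * (1 - rho) / (1 + rho), rel=0.25)

    def test_duplicated_trace_zero_discrepancy(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        out = tracecomp([df, df.copy()])
        assert np.allclose(out["discrepancy"], 0.0)

    def test_burnin_validation(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50)})
        with pytest.raises(ValueError, match="burn-in"):
            tracecomp([df, df], burnin=60)
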