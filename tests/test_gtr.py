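"""GTR generator, transition probabilities, pruning likelihood, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mixclock as mc
from mixclock.gtr import build_gtr, pruning_loglik, transition_probs


def _random_gtr(seed):
    rng = np.random.default_rng(seed)
    rho = rng.dirichlet(np.ones(6) * 3)
    pi = rng.dirichlet(np.ones(4) * 5)
    return mc.GTRParams(rho, pi)


class TestGenerator:
    def test_uniform_params_give_jc(self):
        Q = build_gtr(mc.GTRParams.jc())
        off = Q.Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1 / 3)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_stationarity_balance_and_normalization(self, seed):
        p = _random_gtr(seed)
        Q = build_gtr(p)
        assert np.allclose(p.pi @ Q.Q, 0.0, atol=1e-12)
        flux = p.pi[:, None] * Q.Q
        assert np.allclose(flux, flux.T, atol=1e-12)  # detailed balance
        assert -np.sum(p.pi * np.diag(Q.Q)) == pytest.approx(1.0)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_gtr(mc.GTRParams(np.full(6, 1 / 6), np.array([0.5, 0.5, 0.0, 0.0])))


class TestTransitionProbs:
    def test_zero_length_identity(self, gtr_q):
        assert np.allclose(transition_probs(gtr_q, 0.0), np.eye(4))

    def test_jc_closed_form(self, jc_q):
        for l in (0.01, 0.3, 1.7):
            P = transition_probs(jc_q, l)
            same = 0.25 + 0.75 * np.exp(-4.0 * l / 3.0)
            diff = 0.25 - 0.25 * np.exp(-4.0 * l / 3.0)
            assert np.allclose(np.diag(P), same, atol=1e-12)
            assert np.allclose(P[~np.eye(4, dtype=bool)], diff, atol=1e-12)

    def test_ergodic_limit(self, gtr_q):
        P = transition_probs(gtr_q, 50.0)
        assert np.allclose(P, np.tile(gtr_q.pi, (4, 1)), atol=1e-8)

    def test_negative_length_rejected(self, gtr_q):
        with pytest.raises(ValueError):
            transition_probs(gtr_q, -0.1)


class TestPruning:
    def test_two_taxon_matches_enumeration(self, gtr_q, rng):
        tree = mc.read_newick("(A:1,B:1);")
        l = np.array([0.0, 0.23, 0.41])
        aln = mc.simulate_sequences(tree, l, gtr_q, 40, rng)
        # brute force: site prob = sum_root pi_r P(l_A)[r,a] P(l_B)[r,b]
        PA = transition_probs(gtr_q, l[1] if tree.labels[tree.children[0, 0]] == "A"
                              else l[2])
        order = [tree.children[0, 0], tree.children[0, 1]]
        Ps = [transition_probs(gtr_q, l[v]) for v in order]
        states = {lab: np.argmax(aln.masks()[i], axis=1)
                  for i, lab in enumerate(aln.labels)}
        expected = 0.0
        for s in range(aln.n_sites):
            p = 0.0
            for r in range(4):
                term = gtr_q.pi[r]
                for v, P in zip(order, Ps):
                    term *= P[r, states[tree.labels[v]][s]]
                p += term
            expected += np.log(p)
        got = pruning_loglik(tree, l, aln, gtr_q)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_zero_lengths_identical_sequences(self, gtr_q):
        tree = mc.read_newick("((A:1,B:1):1,C:2);")
        aln = mc.Alignment.from_strings(["A", "B", "C"], ["ACG", "ACG", "ACG"])
        ll = pruning_loglik(tree, np.zeros(5), aln, gtr_q)
        expected = np.sum(np.log(gtr_q.pi[[0, 1, 2]]))
        assert ll == pytest.approx(expected)

    def test_reroot_invariance(self, gtr_q, rng):
        """Same unrooted quartet rooted on two different edges.

        Unrooted edge lengths: A=0.1, B=0.2, C=0.3, D=0.15, internal=0.25.
        By reversibility the likelihood only depends on the unrooted tree.
        """
        def set_lengths(t, by_clade):
            out = np.zeros(t.n_nodes)
            for tips, l in by_clade.items():
                v = (t.tip_label_to_node[tips[0]] if len(tips) == 1
                     else t.mrca(tips))
                out[v] = l
            return out

        # rooted on the internal edge (split 0.15 + 0.10)
        t1 = mc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        l1 = set_lengths(t1, {("A",): 0.1, ("B",): 0.2, ("C",): 0.3,
                              ("D",): 0.15, ("A", "B"): 0.15, ("C", "D"): 0.10})
        # rooted on D's edge (split 0.05 + 0.10)
        t2 = mc.read_newick("(((A:1,B:1):1,C:2):0.5,D:2.5);")
        l2 = set_lengths(t2, {("A",): 0.1, ("B",): 0.2, ("C",): 0.3,
                              ("D",): 0.05, ("A", "B"): 0.25, ("A", "C"): 0.10})
        aln = mc.simulate_sequences(t1, l1, gtr_q, 60, rng)
        ll1 = pruning_loglik(t1, l1, aln, gtr_q)
        ll2 = pruning_loglik(t2, l2, aln, gtr_q)
        assert ll2 == pytest.approx(ll1, abs=1e-8)

    def test_missing_taxon_rejected(self, gtr_q):
        tree = mc.read_newick("((A:1,B:1):1,C:2);")
        aln = mc.Alignment.from_strings(["A", "B", "X"], ["AC", "AC", "AC"])
        with pytest.raises(ValueError, match="mismatch"):
            pruning_loglik(tree, np.full(5, 0.1), aln, gtr_q)


class TestSimulateSequences:
    def test_zero_lengths_all_identical(self, gtr_q, rng):
        tree = mc.read_newick("((A:1,B:1):1,C:2);")
        aln = mc.simulate_sequences(tree, np.zeros(5), gtr_q, 30, rng)
        seqs = aln.sequences()
        assert seqs[0] == seqs[1] == seqs[2]

    def test_saturation_identity(self, gtr_q, rng):
        tree = mc.read_newick("(A:1,B:1);")
        aln = mc.simulate_sequences(tree, np.array([0.0, 40.0, 40.0]),
                                    gtr_q, 40_000, rng)
        codes = aln.codes
        ident = np.mean(codes[0] == codes[1])
        assert ident == pytest.approx(np.sum(gtr_q.pi ** 2), abs=0.01)

    def test_base_frequencies(self, gtr_q, rng):
        tree = mc.read_newick("(A:1,B:1);")
        aln = mc.simulate_sequences(tree, np.array([0.0, 0.1, 0.1]),
                                    gtr_q, 100_000, rng)
        freq = np.array([(aln.codes[0] == c).mean() for c in (1, 2, 4, 8)])
        assert np.allclose(freq, gtr_q.pi, atol=0.01)

    def test_invalid_site_count(self, gtr_q, rng):
        tree = mc.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            mc.simulate_sequences(tree, np.zeros(3), gtr_q, 0, rng)
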