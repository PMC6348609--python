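"""Site model and pruning likelihood against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

import hgtclock as hc
from hgtclock.substitution import (PruningEngine, SiteModelParams,
                                   _eigen_for, discrete_gamma_rates)
from hgtclock.alignment import ProteinAlignment


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 3.7])
    def test_mean_is_one(self, alpha):
        rates = discrete_gamma_rates(alpha, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)

    def test_large_alpha_collapses_to_strict_clock(self):
        # category means deviate by ~1.27/sqrt(alpha), so 1e7 brings all
        # four rates within 1e-3 of the strict-clock limit
        rates = discrete_gamma_rates(1e7, 4)
        assert np.all(np.abs(rates - 1.0) < 1e-3)

    def test_matches_quadrature_oracle(self):
        # category mean = K * integral of t*f(t) between the category quantiles
        alpha, k = 0.5, 4
        cuts = stats.gamma.ppf(np.linspace(0, 1, k + 1), a=alpha,
                               scale=1 / alpha)
        expected = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            val, _ = integrate.quad(
                lambda t: t * stats.gamma.pdf(t, a=alpha, scale=1 / alpha),
                lo, min(hi, 1e3), limit=200)
            expected.append(k * val)
        rates = discrete_gamma_rates(alpha, k)
        assert rates == pytest.approx(expected, abs=1e-6)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)


class TestTransitionMatrix:
    @pytest.mark.parametrize("preset", ["LG", "Poisson"])
    def test_zero_length_is_identity(self, preset):
        m = SiteModelParams(exchangeabilities=preset)
        assert hc.transition_matrix(m, 0.0) == pytest.approx(np.eye(20),
                                                             abs=1e-12)

    def test_rows_are_stochastic(self, rng):
        m = SiteModelParams(exchangeabilities="LG")
        for length in rng.uniform(0, 5, size=10):
            p = hc.transition_matrix(m, float(length))
            assert p.sum(axis=1) == pytest.approx(np.ones(20), abs=1e-10)

    def test_long_branch_reaches_stationarity(self):
        m = SiteModelParams(exchangeabilities="LG")
        p = hc.transition_matrix(m, 50.0)
        pi = m.stationary_frequencies()
        assert np.max(np.abs(p - pi[None, :])) < 1e-4


def _brute_force_loglik(aln, topo, bl, model):
    """Exhaustive enumeration over internal-node state assignments."""
    eigen = _eigen_for(model)
    rates = discrete_gamma_rates(model.alpha, model.categories)
    internal = topo.internal_nodes
    leaves = topo.leaves
    total = 0.0
    for site in range(aln.n_sites):
        site_like = 0.0
        for r in rates:
            pmat = {n: hc.transition_matrix(model, float(bl[n] * r))
                    for n in range(topo.n_nodes)}
            like = 0.0
            for states in itertools.product(range(20), repeat=len(internal)):
                assign = dict(zip(internal, states))
                for leaf in leaves:
                    assign[leaf] = aln.row(topo.labels[leaf])[site]
                term = eigen.pi[assign[topo.root]]
                ok = True
                for n in range(topo.n_nodes):
                    if n == topo.root:
                        continue
                    child_state = assign[n]
                    if child_state >= 20:       # missing: marginalize
                        ok = False
                        break
                    term *= pmat[n][assign[topo.parent[n]], child_state]
                if ok:
                    like += term
            site_like += like / len(rates)
        total += math.log(site_like)
    return total


class TestTreeLogLikelihood:
    def test_invariant_column_zero_lengths(self):
        topo = hc.parse_newick("((A,B),C);")
        aln = ProteinAlignment.from_sequences([("A", "M"), ("B", "M"),
                                               ("C", "M")])
        m = SiteModelParams(exchangeabilities="LG", alpha=1.0, categories=4)
        ll = hc.tree_log_likelihood(aln, topo, np.zeros(topo.n_nodes), m)
        pi = m.stationary_frequencies()
        assert ll == pytest.approx(math.log(pi[hc.alignment.AA_ALPHABET.index("M")]),
                                   abs=1e-10)

    def test_matches_exhaustive_enumeration(self, rng):
        topo = hc.parse_newick("((A,B),C);")
        aln = ProteinAlignment.from_sequences([("A", "MK"), ("B", "ML"),
                                               ("C", "RK")])
        m = SiteModelParams(exchangeabilities="Poisson", alpha=0.7,
                            categories=2)
        bl = np.zeros(topo.n_nodes)
        bl[:-1] = rng.uniform(0.05, 0.6, size=topo.n_nodes - 1)
        fast = hc.tree_log_likelihood(aln, topo, bl, m)
        slow = _brute_force_loglik(aln, topo, bl, m)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_missing_data_enumeration_lg(self, rng):
        topo = hc.parse_newick("(A,B);")
        aln = ProteinAlignment.from_sequences([("A", "M-"), ("B", "MK")])
        m = SiteModelParams(exchangeabilities="LG", alpha=1.3, categories=2)
        bl = np.array([0.2, 0.4, 0.0])
        fast = hc.tree_log_likelihood(aln, topo, bl, m)
        # column 2 has A missing: likelihood is the marginal over A's state,
        # which for a reversible model is just pi-weighted row sums = pi[K]
        eigen = _eigen_for(m)
        k = hc.alignment.AA_ALPHABET.index("K")
        mcol = hc.alignment.AA_ALPHABET.index("M")
        rates = discrete_gamma_rates(m.alpha, m.categories)
        col1 = np.mean([
            sum(eigen.pi[x]
                * hc.transition_matrix(m, 0.2 * r)[x, mcol]
                * hc.transition_matrix(m, 0.4 * r)[x, mcol]
                for x in range(20)) for r in rates])
        col2 = np.mean([
            sum(eigen.pi[x] * hc.transition_matrix(m, 0.4 * r)[x, k]
                for x in range(20)) for r in rates])
        assert fast == pytest.approx(math.log(col1) + math.log(col2),
                                     abs=1e-8)

    def test_pulley_principle_root_relocation(self, rng):
        # reversibility: moving the root along the central branch of a
        # 4-taxon tree leaves the likelihood unchanged
        m = SiteModelParams(exchangeabilities="LG", alpha=0.9, categories=4)
        for _ in range(20):
            x = rng.uniform(0.02, 0.5, size=5)   # A, B, C, D, central
            split = rng.uniform(0.1, 0.9)
            seqs = [("A", "MKVR"), ("B", "MLVR"), ("C", "RKIR"),
                    ("D", "RKIW")]
            aln = ProteinAlignment.from_sequences(seqs)

            t1 = hc.parse_newick("((A,B),(C,D));")
            bl1 = np.zeros(t1.n_nodes)
            bl1[t1.node_of("A")] = x[0]
            bl1[t1.node_of("B")] = x[1]
            bl1[t1.node_of("C")] = x[2]
            bl1[t1.node_of("D")] = x[3]
            ab = hc.mrca(t1, "A", "B")
            cd = hc.mrca(t1, "C", "D")
            bl1[ab] = split * x[4]
            bl1[cd] = (1 - split) * x[4]
            ll1 = hc.tree_log_likelihood(aln, t1, bl1, m)

            t2 = hc.parse_newick("(((A,B),C),D);")  # root on D's branch
            bl2 = np.zeros(t2.n_nodes)
            bl2[t2.node_of("A")] = x[0]
            bl2[t2.node_of("B")] = x[1]
            bl2[t2.node_of("C")] = x[2]
            abc = hc.mrca(t2, "A", "C")
            bl2[hc.mrca(t2, "A", "B")] = x[4]
            bl2[abc] = 0.5 * x[3]
            bl2[t2.node_of("D")] = 0.5 * x[3]
            ll2 = hc.tree_log_likelihood(aln, t2, bl2, m)
            assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_leaf_order_permutation_invariance(self, rng, hgt_fixture):
        fx = hgt_fixture
        m = fx.spec.site_model
        bl = np.zeros(fx.topology.n_nodes)
        bl[:-1] = rng.uniform(0.01, 0.3, size=fx.topology.n_nodes - 1)
        ll = hc.tree_log_likelihood(fx.alignment, fx.topology, bl, m)
        perm = rng.permutation(fx.alignment.n_taxa)
        shuffled = ProteinAlignment(
            taxa=tuple(fx.alignment.taxa[i] for i in perm),
            codes=fx.alignment.codes[perm])
        ll2 = hc.tree_log_likelihood(shuffled, fx.topology, bl, m)
        assert ll == pytest.approx(ll2, abs=1e-9)

    def test_invariant_column_likelihood_decreases_with_tree_length(self):
        topo = hc.parse_newick("((A,B),(C,D));")
        aln = ProteinAlignment.from_sequences(
            [(t, "M") for t in "ABCD"])
        m = SiteModelParams(exchangeabilities="LG", alpha=1.0, categories=4)
        lls = []
        for total in [0.01, 0.1, 0.5, 1.0, 2.0]:
            bl = np.full(topo.n_nodes, total / (topo.n_nodes - 1))
            bl[-1] = 0.0
            lls.append(hc.tree_log_likelihood(aln, topo, bl, m))
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_missing_taxon_rejected(self):
        topo = hc.parse_newick("(A,B);")
        aln = ProteinAlignment.from_sequences([("A", "M")])
        m = SiteModelParams()
        with pytest.raises(ValueError):
            hc.tree_log_likelihood(aln, topo, np.zeros(3), m)


class TestIncrementalEngine:
    def test_propose_matches_full_recompute(self, rng, hgt_fixture):
        fx = hgt_fixture
        eng = PruningEngine(fx.alignment, fx.topology, fx.spec.site_model)
        n = fx.topology.n_nodes
        bl = np.zeros(n)
        bl[:-1] = rng.uniform(0.01, 0.4, size=n - 1)
        ll0 = eng.begin(bl)
        assert ll0 == pytest.approx(eng.log_likelihood(bl), abs=1e-9)
        for _ in range(15):
            bl_new = bl.copy()
            which = rng.choice(n - 1, size=rng.integers(1, 4), replace=False)
            bl_new[which] = rng.uniform(0.01, 0.4, size=which.size)
            ll_prop = eng.propose(bl_new)
            assert ll_prop == pytest.approx(eng.log_likelihood(bl_new),
                                            abs=1e-8)
            if rng.random() < 0.5:
                eng.accept()
                bl = bl_new
            else:
                eng.reject()
                assert eng._loglik == pytest.approx(
                    eng.log_likelihood(bl), abs=1e-8)
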