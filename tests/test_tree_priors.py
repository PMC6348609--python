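"""Uniform and birth-death node-age priors against quadrature, closed-form
and rejection-sampling oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

import hgtclock as hc
from hgtclock.calibrations import Calibration, CalibrationSet
from hgtclock.tree_priors import (TreePriorParams, _bd_kernel_ppf,
                                  bd_age_log_prior, bd_kernel_density,
                                  sample_ages_under_prior,
                                  uniform_age_log_prior)

from conftest import random_chronogram


def _calset_root_only(lo=50.0, hi=150.0, taxa=("L0", "L1")):
    return CalibrationSet(root=Calibration(
        name="root", taxon_a=taxa[0], taxon_b=taxa[1], lower=lo, upper=hi))


class TestUniformPrior:
    def test_flat_given_root_age(self, rng):
        # any two order-compatible age vectors with the same root age have
        # the same density; the normalization depends only on the root age
        for _ in range(5):
            a = random_chronogram(rng, 6, root_age=100.0)
            b = random_chronogram(rng, 6, root_age=100.0)
            assert uniform_age_log_prior(a) == uniform_age_log_prior(b)
            assert np.isfinite(uniform_age_log_prior(a))

    def test_conditional_normalization_scales_with_root(self, rng):
        a = random_chronogram(rng, 6, root_age=100.0)
        doubled = hc.Chronogram(topology=a.topology, ages=a.ages * 2)
        n_inner = len(a.topology.internal_nodes) - 1
        assert uniform_age_log_prior(doubled) - uniform_age_log_prior(a) \
            == pytest.approx(-n_inner * np.log(2))

    def test_inverted_ages_score_minus_inf(self, rng):
        chron = random_chronogram(rng, 5)
        inner = [n for n in chron.topology.internal_nodes
                 if n != chron.topology.root][0]
        chron.ages[inner] = chron.root_age * 2
        assert uniform_age_log_prior(chron) == -np.inf


class TestBdKernel:
    def test_integrates_to_one(self, rng):
        for _ in range(20):
            lam = rng.uniform(0.005, 0.1)
            mu = rng.uniform(0.0, lam * 0.95)
            root_age = rng.uniform(20, 300)
            val, err = integrate.quad(
                lambda t: bd_kernel_density(t, root_age, lam, mu),
                1e-9, root_age - 1e-9, limit=200)
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_pure_birth_closed_form(self, rng):
        lam, root_age = 0.02, 120.0
        ts = rng.uniform(1, 119, size=50)
        norm = 1 - np.exp(-lam * root_age)
        expected = lam * np.exp(-lam * ts) / norm
        got = bd_kernel_density(ts, root_age, lam, 0.0)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_critical_limit_continuous(self):
        lam, root_age = 0.03, 80.0
        ts = np.linspace(5, 75, 7)
        at_limit = bd_kernel_density(ts, root_age, lam, lam)
        approach = bd_kernel_density(ts, root_age, lam, lam * (1 - 1e-9))
        assert at_limit == pytest.approx(approach, abs=1e-6)

    def test_out_of_range_age_rejected(self):
        with pytest.raises(ValueError):
            bd_kernel_density(150.0, 100.0, 0.01, 0.0)

    def test_inverse_cdf_roundtrip(self, rng):
        lam, mu, root_age = 0.04, 0.02, 150.0
        u = rng.uniform(0.01, 0.99, size=200)
        t = _bd_kernel_ppf(u, root_age, lam, mu)
        assert np.all((t > 0) & (t < root_age))
        # CDF(ppf(u)) == u via quadrature on a few points
        for ui, ti in list(zip(u, t))[:5]:
            val, _ = integrate.quad(
                lambda s: bd_kernel_density(s, root_age, lam, mu), 1e-9, ti)
            assert val == pytest.approx(ui, abs=1e-6)


class TestBdAgeLogPrior:
    def test_single_internal_node_is_one_kernel_term(self):
        chron = hc.parse_newick_chronogram("((A:30,B:30):70,C:100);")
        p = TreePriorParams(kind="bd", lam=0.02, mu=0.01)
        expected = np.log(bd_kernel_density(30.0, 100.0, p.lam, p.mu))
        assert bd_age_log_prior(chron, p) == pytest.approx(expected)

    def test_invariant_under_leaf_relabeling(self):
        a = hc.parse_newick_chronogram("((A:30,B:30):70,C:100);")
        b = hc.parse_newick_chronogram("((C:30,A:30):70,B:100);")
        p = TreePriorParams(kind="bd", lam=0.02, mu=0.015)
        assert bd_age_log_prior(a, p) == pytest.approx(bd_age_log_prior(b, p))

    def test_ordering_violation_is_minus_inf(self, rng):
        chron = random_chronogram(rng, 6)
        p = TreePriorParams(kind="bd", lam=0.02, mu=0.0)
        inner = [n for n in chron.topology.internal_nodes
                 if n != chron.topology.root][0]
        chron.ages[inner] = chron.root_age * 1.5
        assert bd_age_log_prior(chron, p) == -np.inf


class TestRejectionSampler:
    def test_samples_respect_all_bounds(self):
        topo = hc.parse_newick("(((L0,L1),L2),L3);")
        calset = _calset_root_only(50, 150, taxa=("L0", "L3"))
        draws = sample_ages_under_prior(
            topo, TreePriorParams(kind="uniform"), calset, 200, seed=3)
        resolved = calset.resolve(topo)
        for chron in draws:
            assert resolved.satisfied(chron.ages)

    def test_seed_reproducibility(self):
        topo = hc.parse_newick("((L0,L1),L2);")
        calset = _calset_root_only(taxa=("L0", "L2"))
        a = sample_ages_under_prior(topo, TreePriorParams(), calset, 20, 5)
        b = sample_ages_under_prior(topo, TreePriorParams(), calset, 20, 5)
        assert all(np.array_equal(x.ages, y.ages) for x, y in zip(a, b))

    def test_mean_root_age_matches_uniform_mean(self):
        topo = hc.parse_newick("(L0,L1);")
        calset = _calset_root_only(60, 140)
        draws = sample_ages_under_prior(topo, TreePriorParams(), calset,
                                        4000, seed=11)
        roots = np.array([c.root_age for c in draws])
        se = (140 - 60) / np.sqrt(12 * roots.size)
        assert roots.mean() == pytest.approx(100.0, abs=4 * se)

    def test_bd_extinction_pushes_ages_tipward(self):
        # extinction makes deep branches long and shallow branches short, so
        # the birth-death kernel concentrates node ages near the tips:
        # BD means are younger than uniform-prior means (the direction the
        # dated models show too: BD posteriors are younger than uniform)
        topo = hc.parse_newick("(((L0,L1),L2),L3);")
        calset = _calset_root_only(90, 110, taxa=("L0", "L3"))
        uni = sample_ages_under_prior(
            topo, TreePriorParams(kind="uniform"), calset, 1500, 7)
        bd = sample_ages_under_prior(
            topo, TreePriorParams(kind="bd", lam=0.01, mu=0.2), calset,
            1500, 7)
        node = hc.mrca(topo, "L0", "L1")
        assert np.mean([c.ages[node] for c in bd]) \
            < np.mean([c.ages[node] for c in uni])
        # and relative to pure birth, extinction shifts mass rootward
        pure = sample_ages_under_prior(
            topo, TreePriorParams(kind="bd", lam=0.05, mu=0.0), calset,
            1500, 7)
        nearly_critical = sample_ages_under_prior(
            topo, TreePriorParams(kind="bd", lam=0.05, mu=0.049), calset,
            1500, 7)
        assert np.mean([c.ages[node] for c in nearly_critical]) \
            > np.mean([c.ages[node] for c in pure])
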