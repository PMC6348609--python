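"""Trace summaries, the OE adequacy statistic, the model grid, and
prior-vs-posterior comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hgtclock as hc
from hgtclock.assessment import (CALIBRATION_STRUCTURES, build_table1_grid,
                                 compare_prior_posterior, oe_statistic,
                                 run_model_grid, score_recovery,
                                 summarize_node_ages)
from hgtclock.mcmc import McmcConfig, Trace


def _trace_from(values: dict) -> Trace:
    return Trace(data=pd.DataFrame(values))


class TestSummarizeNodeAges:
    def test_constant_trace(self):
        tr = _trace_from({"age_3": np.full(100, 42.0)})
        s = summarize_node_ages(tr)[0]
        assert (s.mean, s.ci_low, s.ci_high) == (42.0, 42.0, 42.0)

    def test_uniform_quantiles(self):
        rng = np.random.default_rng(5)
        tr = _trace_from({"age_0": rng.uniform(size=100_000)})
        s = summarize_node_ages(tr)[0]
        assert s.ci_low == pytest.approx(0.025, abs=0.005)
        assert s.ci_high == pytest.approx(0.975, abs=0.005)

    def test_quantile_rule_regression_locked(self):
        # linear (type-7) interpolation on a small fixed sample
        tr = _trace_from({"age_1": np.arange(1.0, 11.0)})
        s = summarize_node_ages(tr)[0]
        assert s.ci_low == pytest.approx(1.225)
        assert s.ci_high == pytest.approx(9.775)


# the sixteen published adequacy rows: (CI, expected range, OE percent);
# CIs as printed (upper-lower order is accepted and sorted internally)
PUBLISHED_OE_ROWS = [
    # AB-split calibration structure 1, Ascomycota
    ((728, 580), (715, 408), 8.8),
    ((630, 481), (715, 408), 0.0),
    ((592, 391), (715, 408), 8.5),
    ((457, 267), (715, 408), 74.2),
    # structure 1, Basidiomycota
    ((749, 602), (655, 400), 63.9),
    ((698, 559), (655, 400), 30.9),
    ((650, 443), (655, 400), 0.0),
    ((572, 349), (655, 400), 22.9),
    # structure 3, Ascomycota
    ((731, 590), (715, 408), 11.3),
    ((637, 484), (715, 408), 0.0),
    ((616, 397), (715, 408), 5.0),
    ((447, 276), (715, 408), 77.2),
    # structure 3, Basidiomycota
    ((754, 607), (655, 400), 67.3),
    ((687, 554), (655, 400), 24.1),
    ((674, 430), (655, 400), 7.8),
    ((570, 369), (655, 400), 15.4),
]


class TestOeStatistic:
    @pytest.mark.parametrize("ci,expected,oe", PUBLISHED_OE_ROWS)
    def test_reproduces_published_adequacy_values(self, ci, expected, oe):
        assert oe_statistic(ci, expected) == pytest.approx(oe, abs=0.05)

    def test_identical_intervals_zero(self):
        assert oe_statistic((400, 655), (400, 655)) == 0.0

    def test_affine_rescaling_invariance(self, rng):
        for _ in range(20):
            a, b = sorted(rng.uniform(0, 1000, size=2))
            c, d = sorted(rng.uniform(0, 1000, size=2))
            if a == b or c == d:
                continue
            scale = rng.uniform(0.1, 10)
            shift = rng.uniform(-100, 100)
            base = oe_statistic((a, b), (c, d))
            moved = oe_statistic((a * scale + shift, b * scale + shift),
                                 (c * scale + shift, d * scale + shift))
            assert moved == pytest.approx(base, abs=0.1)

    def test_enlarging_expected_never_increases_oe(self, rng):
        for _ in range(20):
            ci = tuple(sorted(rng.uniform(0, 500, size=2)))
            lo, hi = sorted(rng.uniform(0, 500, size=2))
            if ci[0] == ci[1] or lo == hi:
                continue
            wider = (lo - rng.uniform(0, 50), hi + rng.uniform(0, 50))
            assert oe_statistic(ci, wider) <= oe_statistic(ci, (lo, hi))

    def test_zero_length_ci_rejected(self):
        with pytest.raises(ValueError):
            oe_statistic((500, 500), (400, 655))


class TestModelGrid:
    def test_full_grid_structure(self):
        grid = build_table1_grid()
        assert len(grid.models) == 16
        assert len(grid.variants()) == 32
        by_id = {m.model_id: m for m in grid.models}
        assert (by_id[1].tree_prior, by_id[1].clock_model) == ("uniform", "ln")
        assert (by_id[5].tree_prior, by_id[5].clock_model) == ("uniform", "ugam")
        assert (by_id[9].tree_prior, by_id[9].clock_model) == ("bd", "ugam")
        assert (by_id[13].tree_prior, by_id[13].clock_model) == ("bd", "ln")
        for m in grid.models:
            assert m.calibration_structure == (m.model_id - 1) % 4 + 1

    def test_subset_selection_order_independent(self):
        a = build_table1_grid(model_ids=[6, 2])
        b = build_table1_grid(model_ids=[2, 6])
        assert a == b
        assert [m.model_id for m in a.models] == [2, 6]

    def test_unknown_model_id_rejected(self):
        with pytest.raises(ValueError):
            build_table1_grid(model_ids=[17])

    def test_grid_runs_and_reproduces(self, hgt_fixture):
        fx = hgt_fixture
        grid = build_table1_grid(model_ids=[2, 10], include_prior_only=True)
        cfg = McmcConfig(generations=300, thinning=3, seed=9)
        res1, man1 = run_model_grid(fx.topology, fx.alignment,
                                    fx.calibrations, grid, cfg,
                                    fx.spec.site_model)
        res2, man2 = run_model_grid(fx.topology, fx.alignment,
                                    fx.calibrations, grid, cfg,
                                    fx.spec.site_model)
        assert sorted(res1["model"].unique()) == ["10", "10p", "2", "2p"]
        pd.testing.assert_frame_equal(res1, res2)
        assert man1[0]["calibrations"] == ["root"] + \
            list(CALIBRATION_STRUCTURES[2])
        assert {"oe_percent", "ess_min", "max_discrepancy"} <= set(res1)

    def test_two_chain_grid_reports_discrepancy(self, hgt_fixture):
        fx = hgt_fixture
        grid = build_table1_grid(model_ids=[6], include_prior_only=False)
        cfg = McmcConfig(generations=2000, thinning=4, seed=9)
        res, man = run_model_grid(fx.topology, fx.alignment, fx.calibrations,
                                  grid, cfg, fx.spec.site_model, n_chains=2)
        assert np.isfinite(man[0]["max_discrepancy"])
        assert man[0]["max_discrepancy"] >= 0.0
        # OE is scored for every node with a literature window
        scored = res[res["oe_percent"].notna()]
        assert len(scored) == 4            # root, ab/fossil, two crowns


class TestComparePriorPosterior:
    def test_identical_traces(self):
        tr = _trace_from({"age_0": np.linspace(0, 1, 500)})
        rep = compare_prior_posterior(tr, tr, 0)
        assert rep.mean_shift == 0.0
        assert rep.overlap == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = _trace_from({"age_0": np.linspace(0, 1, 500)})
        b = _trace_from({"age_0": np.linspace(10, 11, 500)})
        assert compare_prior_posterior(a, b, 0).overlap == 0.0

    def test_gaussian_overlap_matches_closed_form(self):
        # two unit-variance Gaussians d apart overlap by 2*Phi(-d/2)
        rng = np.random.default_rng(17)
        d = 1.5
        a = _trace_from({"age_0": rng.normal(0, 1, 200_000)})
        b = _trace_from({"age_0": rng.normal(d, 1, 200_000)})
        rep = compare_prior_posterior(a, b, 0, bins=100)
        assert rep.overlap == pytest.approx(2 * stats.norm.cdf(-d / 2),
                                            abs=0.02)


class TestScoreRecovery:
    def test_counts_hits(self):
        summ = [hc.NodeSummary(node=0, mean=5, ci_low=4, ci_high=6),
                hc.NodeSummary(node=1, mean=5, ci_low=4, ci_high=6)]
        assert score_recovery(summ, {0: 5.0, 1: 10.0}) == 0.5

    def test_no_overlap_with_truth_rejected(self):
        summ = [hc.NodeSummary(node=0, mean=5, ci_low=4, ci_high=6)]
        with pytest.raises(ValueError):
            score_recovery(summ, {7: 1.0})
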