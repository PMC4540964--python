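"""Trait simulation and parametric-bootstrap model choice."""
import math

import numpy as np
import pytest

from crmou.oufit import BMParams, OUParams
from crmou.pmc import (distribution_overlap, pmc_power, simulate_trait,
                       simulate_traits)


class TestSimulateTrait:
    def test_identical_seed_identical_output(self, tree12, paintings12):
        p = OUParams(0.05, 1.0, {"base": 2.0})
        a = simulate_traits(tree12, paintings12["M0"], p, 5, 31)
        b = simulate_traits(tree12, paintings12["M0"], p, 5, 31)
        assert a.equals(b)

    def test_seed_required(self, tree12, paintings12):
        with pytest.raises(ValueError):
            simulate_trait(tree12, paintings12["M0"],
                           OUParams(0.05, 1.0, {"base": 0.0}), None)

    def test_strong_selection_pins_tips_to_optima(self):
        from crmou.phylo import paint_tips, parse_newick
        t = parse_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
        painting = paint_tips(t, {"C", "D"}, "MX")
        params = OUParams(100.0, 1.0, {"base": -4.0, "shift": 4.0})
        sims = simulate_traits(t, painting, params, 400, 8)
        near = ((sims[["A", "B"]] + 4.0).abs() < 0.3).to_numpy().mean()
        assert near > 0.98
        near = ((sims[["C", "D"]] - 4.0).abs() < 0.3).to_numpy().mean()
        assert near > 0.98

    def test_bm_tip_variance_matches_closed_form(self, tree5):
        from crmou.phylo import bm_painting
        sims = simulate_traits(tree5, bm_painting(tree5), BMParams(0.0, 1.0),
                               10_000, 55)
        # tip A sits at depth 2 => Var = sigma^2 * 2
        v = sims["A"].var()
        se = 2.0 * math.sqrt(2.0 / 10_000)
        assert abs(v - 2.0) < 3 * se + 0.02

    def test_ou_tip_variance_matches_closed_form(self, tree5, paintings12):
        from crmou.phylo import m0_painting
        alpha, s2 = 0.7, 1.3
        sims = simulate_traits(tree5, m0_painting(tree5),
                               OUParams(alpha, s2, {"base": 0.0}), 10_000, 56)
        depth = tree5.tip("A").time
        expected = s2 / (2 * alpha) * (1 - math.exp(-2 * alpha * depth))
        v = sims["A"].var()
        assert abs(v - expected) < 4 * expected * math.sqrt(2.0 / 10_000)

    def test_mean_loglik_matches_analytic_entropy(self, tree5):
        # E[log density at the truth] = -(n ln 2pi + ln|V| + n)/2
        from crmou.oufit import hansen_loglik
        from crmou.phylo import m0_painting
        from oracles import ou_moments_by_propagation
        painting = m0_painting(tree5)
        params = OUParams(0.6, 1.1, {"base": 1.0})
        labels, mean, cov = ou_moments_by_propagation(
            tree5, painting, 0.6, 1.1, {"base": 1.0}, x0=1.0)
        n = len(labels)
        expected = -0.5 * (n * math.log(2 * math.pi)
                           + math.log(np.linalg.det(cov)) + n)
        sims = simulate_traits(tree5, painting, params, 400, 2121)
        lls = [hansen_loglik(tree5, painting, row, params)
               for _, row in sims.iterrows()]
        se = np.std(lls, ddof=1) / math.sqrt(len(lls))
        assert abs(np.mean(lls) - expected) < 3 * se


class TestPmcPower:
    def test_same_model_pair_overlaps_fully(self, tree12, paintings12):
        params = OUParams(0.05, 1.0, {"base": 3.0})
        trait = simulate_trait(tree12, paintings12["M0"], params, 17)
        res = pmc_power(tree12, trait, paintings12["M0"], paintings12["M0"],
                        n_boot=40, seed=18)
        assert res.delta_obs == pytest.approx(0.0, abs=1e-9)
        assert res.overlap > 0.95

    def test_strong_shift_detected_beyond_null_quantile(self, tree12,
                                                        paintings12):
        alpha = math.log(2) / 20
        sd = 1.0
        params = OUParams(alpha, 2 * alpha * sd ** 2,
                          {"base": 3.0, "shift": 3.0 + 5 * sd})
        trait = simulate_trait(tree12, paintings12["M10"], params, 19)
        # a = M0 (null), b = M10: delta = 2(logL_M0 - logL_M10)
        res = pmc_power(tree12, trait, paintings12["M0"], paintings12["M10"],
                        n_boot=60, seed=20)
        # observed delta far below the null distribution of data simulated
        # under M0 => the observed trait rejects the single optimum
        assert res.quantile_null <= 0.05
        assert res.delta_obs < np.percentile(res.delta_null, 5)

    def test_bit_identical_rerun(self, tree12, paintings12):
        params = OUParams(0.05, 1.0, {"base": 3.0})
        trait = simulate_trait(tree12, paintings12["M0"], params, 21)
        kw = dict(n_boot=25, seed=22)
        r1 = pmc_power(tree12, trait, paintings12["M0"], paintings12["M10"],
                       **kw)
        r2 = pmc_power(tree12, trait, paintings12["M0"], paintings12["M10"],
                       **kw)
        np.testing.assert_array_equal(r1.delta_null, r2.delta_null)
        np.testing.assert_array_equal(r1.delta_alt, r2.delta_alt)
        assert r1.overlap == r2.overlap

    def test_delta_null_nonnegative_when_b_nests_a(self, tree12, paintings12):
        # a = M0 nested in b = M10: delta = 2(logL_M0 - logL_M10) <= 0
        params = OUParams(0.05, 1.0, {"base": 3.0})
        trait = simulate_trait(tree12, paintings12["M0"], params, 23)
        res = pmc_power(tree12, trait, paintings12["M0"], paintings12["M10"],
                        n_boot=40, seed=24)
        assert np.mean(res.delta_null <= 1e-6) > 0.95

    def test_report_mentions_overlap(self, tree12, paintings12):
        params = OUParams(0.05, 1.0, {"base": 3.0})
        trait = simulate_trait(tree12, paintings12["M0"], params, 25)
        res = pmc_power(tree12, trait, paintings12["M0"], paintings12["M10"],
                        n_boot=20, seed=26)
        assert "overlap" in res.report()
        assert len(res.to_frame()) == res.delta_null.size + res.delta_alt.size


class TestOverlapStatistic:
    def test_identical_samples_full_overlap(self, rng):
        x = rng.normal(0, 1, 500)
        assert distribution_overlap(x, x) == pytest.approx(1.0)

    def test_disjoint_samples_no_overlap(self, rng):
        a = rng.normal(-50, 0.1, 500)
        b = rng.normal(50, 0.1, 500)
        assert distribution_overlap(a, b) < 0.05

    def test_degenerate_point_masses(self):
        assert distribution_overlap(np.zeros(10), np.zeros(10)) == 1.0
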