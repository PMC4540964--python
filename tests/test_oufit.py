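"""BM / OU / Hansen likelihoods and maximum-likelihood fitting."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from crmou.oufit import (BMParams, OUParams, bm_loglik, fit_model, fit_region,
                         fits_frame, hansen_loglik)
from crmou.phylo import m0_painting, paint_tips, parse_newick
from crmou.pmc import simulate_traits
from oracles import ou_moments_by_propagation, random_tree_newick


class TestBmLoglik:
    def test_two_tip_star_closed_form(self):
        t = parse_newick("(A:1.0,B:1.0);")
        ll = bm_loglik(t, {"A": 0.0, "B": 0.0}, x0=0.0, sigma_sq=1.0)
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-12)
        ll = bm_loglik(t, {"A": 1.0, "B": -1.0}, x0=0.0, sigma_sq=1.0)
        assert ll == pytest.approx(-math.log(2 * math.pi) - 1.0, abs=1e-12)

    def test_sister_tip_covariance_matches_monte_carlo(self, tree5):
        # A and B share a stem of length 1 => Cov = sigma^2 * 1
        sims = simulate_traits(tree5, m0_painting(tree5).rederive(tree5),
                               BMParams(0.0, 1.0), 10_000, 77)
        cov = np.cov(sims["A"], sims["B"])[0, 1]
        se = 1.0 / math.sqrt(10_000) * 2.0  # rough SE of a covariance
        assert abs(cov - 1.0) < 3 * se + 0.05

    def test_invalid_sigma_rejected(self, tree5):
        with pytest.raises(ValueError):
            bm_loglik(tree5, {t: 0.0 for t in tree5.tip_labels}, 0.0, 0.0)


class TestHansenLoglik:
    def test_two_tip_star_closed_form(self):
        t = parse_newick("(A:1.0,B:1.0);")
        p = m0_painting(t)
        ll = hansen_loglik(t, p, {"A": 0.0, "B": 0.0},
                           OUParams(1.0, 2.0, {"base": 0.0}))
        var = (2.0 / 2.0) * (1.0 - math.exp(-2.0))
        assert var == pytest.approx(0.864665, abs=1e-6)
        assert ll == pytest.approx(-math.log(2 * math.pi * var), abs=1e-9)

    def test_small_alpha_limit_equals_bm(self, tree5, rng):
        p = m0_painting(tree5)
        for _ in range(20):
            y = dict(zip(tree5.tip_labels, rng.normal(0.5, 2.0, 5)))
            llb = bm_loglik(tree5, y, x0=0.5, sigma_sq=1.3)
            llo = hansen_loglik(tree5, p, y,
                                OUParams(1e-10, 1.3, {"base": 0.5}))
            assert abs(llb - llo) < 1e-5

    def test_strong_selection_stationary_limit(self):
        t = parse_newick("(A:1.0,B:1.0,C:1.0);")
        p = paint_tips(t, {"A", "B", "C"}, "ALL")
        alpha, c = 50.0, 4.2
        # all optima equal c: tip mean -> c, tip variance -> sigma^2/(2 alpha)
        labels, mean, cov = ou_moments_by_propagation(
            t, p, alpha, 1.0, {"shift": c, "base": c}, x0=c)
        assert np.allclose(mean, c, atol=1e-6)
        assert np.allclose(np.diag(cov), 1.0 / (2 * alpha), atol=1e-6)

    def test_matches_propagation_oracle_on_random_trees(self, rng):
        for _ in range(25):
            n_tips = int(rng.integers(3, 9))
            tree = parse_newick(random_tree_newick(rng, n_tips))
            shift = set(rng.choice(tree.tip_labels,
                                   size=int(rng.integers(1, n_tips)),
                                   replace=False))
            painting = paint_tips(tree, shift, "MX")
            alpha = float(rng.uniform(0.1, 3.0))
            sigma_sq = float(rng.uniform(0.2, 2.0))
            theta = {"base": float(rng.normal(0, 2)),
                     "shift": float(rng.normal(0, 2))}
            x0 = theta[painting.root_regime]
            labels, mean, cov = ou_moments_by_propagation(
                tree, painting, alpha, sigma_sq, theta, x0)
            y = mean + rng.normal(0, 0.5, len(labels))
            expected = multivariate_normal.logpdf(y, mean=mean, cov=cov)
            got = hansen_loglik(tree, painting, dict(zip(labels, y)),
                                OUParams(alpha, sigma_sq, theta))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_tip_ordering_in_trait(self, tree5, rng):
        p = paint_tips(tree5, {"D", "E"}, "MX")
        vals = dict(zip(tree5.tip_labels, rng.normal(0, 1, 5)))
        params = OUParams(0.8, 1.0, {"base": 0.0, "shift": 2.0})
        ll1 = hansen_loglik(tree5, p, vals, params)
        shuffled = dict(reversed(list(vals.items())))
        ll2 = hansen_loglik(tree5, p, shuffled, params)
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_alpha_zero_rejected(self, tree5):
        with pytest.raises(ValueError):
            OUParams(0.0, 1.0, {"base": 0.0})


class TestFitModel:
    def test_constant_trait_m0(self, tree12, paintings12):
        f = fit_model(tree12, paintings12["M0"],
                      {t: 4.2 for t in tree12.tip_labels})
        assert f.theta_base == pytest.approx(4.2, abs=1e-9)
        assert f.status == "degenerate"
        assert f.k == 3
        assert f.aic == pytest.approx(2 * 3 - 2 * f.loglik, abs=1e-12)

    def test_parameter_counts_and_aic_identity(self, tree12, paintings12, rng):
        y = dict(zip(tree12.tip_labels, rng.normal(3, 1, 12)))
        fits = fit_region(tree12, y, [paintings12[m]
                                      for m in ("BM", "M0", "M10")])
        assert fits["BM"].k == 2 and fits["M0"].k == 3 and fits["M10"].k == 4
        for f in fits.values():
            assert f.aic == pytest.approx(2 * f.k - 2 * f.loglik, abs=1e-9)

    def test_nesting_inequality(self, tree12, paintings12, rng):
        shift_models = [f"M{i}" for i in range(1, 11)]
        for _ in range(5):
            y = dict(zip(tree12.tip_labels, rng.normal(3, 1.2, 12)))
            fits = fit_region(tree12, y,
                              [paintings12[m] for m in ["M0"] + shift_models])
            for m in shift_models:
                assert fits[m].loglik >= fits["M0"].loglik - 1e-6

    def test_shift_recovery_under_strong_shift(self, tree12, paintings12):
        alpha = math.log(2) / 20
        params = OUParams(alpha, 2 * alpha * 1.0,
                          {"base": 2.0, "shift": 7.0})
        sims = simulate_traits(tree12, paintings12["M10"], params, 30, 99)
        est = []
        for _, row in sims.iterrows():
            f = fit_model(tree12, paintings12["M10"], row)
            est.append(f.theta_shift)
        est = np.array(est)
        # theta_shift estimates scatter around the generating optimum 7
        assert 5.0 < np.median(est) < 9.0
        assert np.mean((est > 4.0) & (est < 10.0)) > 0.8

    def test_bm_data_drives_m0_alpha_toward_lower_bound(self, tree12,
                                                        paintings12):
        # alpha is weakly identified on 12 tips: under BM data the fitted
        # OU alpha concentrates at negligible selection, with a point mass
        # at the hard optimizer bound
        sims = simulate_traits(tree12, paintings12["BM"],
                               BMParams(0.0, 1.0), 40, 123)
        alphas = np.array([fit_model(tree12, paintings12["M0"], row).alpha
                           for _, row in sims.iterrows()])
        assert np.mean(alphas <= 1.1e-8) >= 0.25
        assert np.median(alphas) * tree12.height < 1.0

    def test_missing_species_pruned_and_refit(self, tree12, paintings12):
        y = {t: 1.0 + i * 0.1 for i, t in enumerate(tree12.tip_labels)}
        y["Dmoj"] = np.nan
        f = fit_model(tree12, paintings12["M4"], pd.Series(y))
        assert f.ok
        assert f.n_tips == 11

    def test_all_shift_tips_missing_is_untestable(self, tree12, paintings12):
        y = {t: 1.0 for t in tree12.tip_labels if t != "Dvir"}
        f = fit_model(tree12, paintings12["M10"], y)
        assert f.status == "untestable"
        assert not f.ok
        assert math.isnan(f.loglik)

    def test_too_few_tips_rejected(self, tree12, paintings12):
        with pytest.raises(ValueError):
            fit_model(tree12, paintings12["M0"], {"Dmel": 1.0, "Dvir": 2.0})

    def test_fits_frame_schema(self, tree12, paintings12, rng):
        y = dict(zip(tree12.tip_labels, rng.normal(0, 1, 12)))
        fits = {"r1": fit_region(tree12, y, [paintings12["M0"],
                                             paintings12["M10"]])}
        df = fits_frame(fits)
        assert set(df["model"]) == {"M0", "M10"}
        assert {"alpha", "sigma_sq", "loglik", "aic", "status"} <= set(df.columns)
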