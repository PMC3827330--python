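"""Latent bivariate-normal likelihood and the full correlation estimator."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from cohortpath.latentcorr import (
    LatentPairModel,
    VariableSpec,
    fit_latent_correlation,
    pair_loglik,
    to_interval,
)
from cohortpath.mcmc import McmcConfig

from conftest import bvn_sample

CONT = VariableSpec("x")
CONT_Y = VariableSpec("y")


class TestVariableSpec:
    def test_censored_needs_a_bound(self):
        with pytest.raises(ValueError, match="ceiling or floor"):
            VariableSpec("v", "censored_continuous")

    def test_ordinal_needs_three_categories(self):
        with pytest.raises(ValueError, match="n_categories"):
            VariableSpec("v", "ordinal", n_categories=2)

    def test_binary_forces_two_categories(self):
        assert VariableSpec("v", "binary").n_categories == 2

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown measurement kind"):
            VariableSpec("v", "categorical")


class TestLatentPairModel:
    def test_rho_bounded_away_from_one(self):
        with pytest.raises(ValueError):
            LatentPairModel(rho=1.0)

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            LatentPairModel(tau_x=np.array([0.5, 0.2]))


class TestToInterval:
    def test_continuous_point(self):
        m = LatentPairModel()
        assert to_interval(27.1, CONT, m) == pytest.approx(27.1)

    def test_point_standardised(self):
        m = LatentPairModel(mu_x=10.0, sigma_x=2.0)
        assert to_interval(14.0, CONT, m) == pytest.approx(2.0)

    def test_value_at_ceiling_becomes_upper_tail(self):
        spec = VariableSpec("a", "censored_continuous", ceiling=30.0)
        m = LatentPairModel(mu_x=28.0, sigma_x=2.0)
        lo, hi = to_interval(30.0, spec, m)
        assert lo == pytest.approx(1.0) and hi == math.inf

    def test_binary_positive_state(self):
        spec = VariableSpec("b", "binary")
        m = LatentPairModel(tau_x=np.array([0.4]))
        assert to_interval(2, spec, m) == (pytest.approx(0.4), math.inf)

    def test_ordinal_intervals_tile_the_line(self):
        spec = VariableSpec("o", "ordinal", n_categories=4)
        m = LatentPairModel(tau_x=np.array([-1.0, 0.0, 1.5]))
        ivals = [to_interval(k, spec, m) for k in (1, 2, 3, 4)]
        assert ivals[0][0] == -math.inf and ivals[-1][1] == math.inf
        for (a, b), (c, d) in zip(ivals, ivals[1:]):
            assert b == c

    def test_out_of_range_category(self):
        spec = VariableSpec("o", "ordinal", n_categories=4)
        m = LatentPairModel(tau_x=np.array([-1.0, 0.0, 1.5]))
        with pytest.raises(ValueError, match="out of range"):
            to_interval(5, spec, m)


class TestPairLoglik:
    def test_independent_margins_factorise(self, rng):
        x, y = rng.normal(1.0, 2.0, 30), rng.normal(-1.0, 0.5, 30)
        m = LatentPairModel(mu_x=1.0, sigma_x=2.0, mu_y=-1.0, sigma_y=0.5, rho=0.0)
        ll = pair_loglik(x, y, CONT, CONT_Y, m)
        expected = norm.logpdf(x, 1.0, 2.0).sum() + norm.logpdf(y, -1.0, 0.5).sum()
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_missing_pairs_dropped(self, rng):
        x = np.array([0.1, 0.5, np.nan, 1.0])
        y = np.array([0.2, np.nan, 0.3, -0.4])
        m = LatentPairModel(rho=0.2)
        keep = np.array([0, 3])
        assert pair_loglik(x, y, CONT, CONT_Y, m) == pytest.approx(
            pair_loglik(x[keep], y[keep], CONT, CONT_Y, m)
        )

    def test_matches_numerical_integration_on_censored_data(self, rng):
        """Independent quadrature oracle over the censored regions, n=20."""
        rho, mu, sigma = 0.55, (0.3, -0.2), (1.2, 0.8)
        x, y = bvn_sample(rng, 20, rho, mu, sigma)
        cx = float(np.quantile(x, 0.6))
        cy = float(np.quantile(y, 0.7))
        xs, ys = np.minimum(x, cx), np.minimum(y, cy)
        sx = VariableSpec("x", "censored_continuous", ceiling=cx)
        sy = VariableSpec("y", "censored_continuous", ceiling=cy)
        model = LatentPairModel(
            mu_x=mu[0], sigma_x=sigma[0], mu_y=mu[1], sigma_y=sigma[1], rho=rho
        )
        cov = [
            [sigma[0] ** 2, rho * sigma[0] * sigma[1]],
            [rho * sigma[0] * sigma[1], sigma[1] ** 2],
        ]
        pdf = multivariate_normal(mean=list(mu), cov=cov).pdf

        def term(xi, yi):
            if xi < cx and yi < cy:
                return math.log(pdf([xi, yi]))
            if xi >= cx and yi < cy:
                val, _ = integrate.quad(lambda t: pdf([t, yi]), cx, mu[0] + 12 * sigma[0])
                return math.log(val)
            if xi < cx and yi >= cy:
                val, _ = integrate.quad(lambda t: pdf([xi, t]), cy, mu[1] + 12 * sigma[1])
                return math.log(val)
            val, _ = integrate.dblquad(
                lambda t, s: pdf([s, t]),
                cx, mu[0] + 12 * sigma[0],
                cy, mu[1] + 12 * sigma[1],
            )
            return math.log(val)

        oracle = sum(term(xi, yi) for xi, yi in zip(xs, ys))
        assert pair_loglik(xs, ys, sx, sy, model) == pytest.approx(oracle, abs=1e-6)

    def test_uninformative_pair_contributes_nothing(self):
        # a 1-category-like situation: both margins binary with extreme
        # thresholds makes the single cell near-certain, log prob near 0
        sx = VariableSpec("x", "binary")
        sy = VariableSpec("y", "binary")
        m = LatentPairModel(rho=0.3, tau_x=np.array([-8.0]), tau_y=np.array([-8.0]))
        ll = pair_loglik(np.array([2.0]), np.array([2.0]), sx, sy, m)
        assert ll == pytest.approx(0.0, abs=1e-10)

    def test_zero_probability_cell_returns_neg_inf(self):
        sx = VariableSpec("x", "binary")
        sy = VariableSpec("y", "binary")
        # category below an extreme threshold has essentially zero mass
        m = LatentPairModel(rho=0.0, tau_x=np.array([-40.0]), tau_y=np.array([0.0]))
        ll = pair_loglik(np.array([1.0]), np.array([1.0]), sx, sy, m)
        assert ll == -math.inf


class TestFitLatentCorrelation:
    def test_matches_pearson_without_censoring(self, rng):
        x, y = bvn_sample(rng, 2000, 0.5)
        est = fit_latent_correlation(x, y, CONT, CONT_Y, McmcConfig(seed=11))
        assert est.rho == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.05)
        assert est.ci[0] < est.rho < est.ci[1]

    def test_symmetry_in_argument_order(self, rng):
        x, y = bvn_sample(rng, 800, 0.6)
        c = float(np.quantile(x, 0.5))
        xs = np.minimum(x, c)
        sx = VariableSpec("x", "censored_continuous", ceiling=c)
        e1 = fit_latent_correlation(xs, y, sx, CONT_Y, McmcConfig(seed=21))
        e2 = fit_latent_correlation(y, xs, CONT_Y, sx, McmcConfig(seed=22))
        assert e1.rho == pytest.approx(e2.rho, abs=3 * (e1.se + e2.se))

    def test_censoring_correction_beats_naive_pearson(self, rng):
        x, y = bvn_sample(rng, 1000, 0.6)
        c = float(np.quantile(x, 0.4))  # 60% of mass at the ceiling
        xs = np.minimum(x, c)
        sx = VariableSpec("x", "censored_continuous", ceiling=c)
        est = fit_latent_correlation(xs, y, sx, CONT_Y, McmcConfig(seed=31))
        naive = np.corrcoef(xs, y)[0, 1]
        assert est.rho > naive
        assert est.rho == pytest.approx(0.6, abs=0.12)

    def test_two_step_thresholds_agree_with_one_step(self, rng):
        x, y = bvn_sample(rng, 1500, 0.5)
        bx = (x > 0).astype(float) + 1
        by = (y > 0.2).astype(float) + 1
        sx, sy = VariableSpec("x", "binary"), VariableSpec("y", "binary")
        one = fit_latent_correlation(bx, by, sx, sy, McmcConfig(seed=41))
        two = fit_latent_correlation(bx, by, sx, sy, McmcConfig(seed=42), thresholds="fixed")
        assert one.rho == pytest.approx(two.rho, abs=3 * (one.se + two.se))

    def test_reports_pairwise_n(self, rng):
        x, y = bvn_sample(rng, 100, 0.4)
        x[:20] = np.nan
        est = fit_latent_correlation(
            x, y, CONT, CONT_Y, McmcConfig(chain_length=600, estimate_window=200, seed=1)
        )
        assert est.n_pairs == 80 and est.n_dropped == 20

    def test_too_few_pairs_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="at least 10"):
            fit_latent_correlation(x, x + 1.0, CONT, CONT_Y)

    def test_single_valued_margin_rejected(self):
        x = np.ones(50)
        y = np.arange(50.0)
        with pytest.raises(ValueError, match="single observed value"):
            fit_latent_correlation(x, y, CONT, CONT_Y)

    def test_all_missing_rejected(self):
        x = np.full(30, np.nan)
        with pytest.raises(ValueError, match="no pairwise-complete"):
            fit_latent_correlation(x, x, CONT, CONT_Y)

    def test_estimate_format_matches_table_style(self, rng):
        x, y = bvn_sample(rng, 300, 0.5)
        est = fit_latent_correlation(
            x, y, CONT, CONT_Y, McmcConfig(chain_length=800, estimate_window=300, seed=3)
        )
        import re

        assert re.fullmatch(
            r"-?\d\.\d{3} ± \d\.\d{3} \(-?\d\.\d{3} to -?\d\.\d{3}\)", est.format()
        )
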