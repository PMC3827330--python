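"""Synthetic-cohort generator: simplex structure, selection, observation,
uptake, and the retained generating truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from cohortpath.simulate import (
    StageObservation,
    SyntheticConfig,
    Uptake,
    apply_selection,
    apply_uptake,
    cohort_1990_like,
    generate_cohort,
    generate_latent,
    observe_stage,
    simplex_correlation,
    uclms_like,
)


class TestSimplexCorrelation:
    def test_product_closure_exact(self):
        m = simplex_correlation([0.6, 0.5, 0.7])
        for i in range(4):
            for j in range(i + 1, 4):
                for k in range(j + 1, 4):
                    assert m[i, k] == pytest.approx(m[i, j] * m[j, k], abs=1e-14)

    def test_lag1_values_on_diagonal_band(self):
        m = simplex_correlation([0.6, 0.5])
        assert m[0, 1] == 0.6 and m[1, 2] == 0.5 and m[0, 2] == pytest.approx(0.3)


class TestGenerateLatent:
    def test_zero_lag1_gives_independent_stages(self):
        cfg = SyntheticConfig(n_applicants=4000, stages=["a", "b", "c"],
                              lag1=[0.0, 0.0], seed=1)
        z = generate_latent(cfg)
        r = z.corr().to_numpy()
        off = r[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 3 / np.sqrt(4000))

    def test_product_rule_within_mc_error(self):
        cfg = SyntheticConfig(n_applicants=20000, stages=["a", "b", "c"],
                              lag1=[0.6, 0.5], seed=2)
        z = generate_latent(cfg)
        assert z["a"].corr(z["c"]) == pytest.approx(0.30, abs=0.03)

    def test_seed_reproducibility(self):
        cfg = SyntheticConfig(n_applicants=100, stages=["a", "b"], lag1=[0.5], seed=9)
        assert generate_latent(cfg).equals(generate_latent(cfg))

    def test_non_pd_matrix_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        cfg = SyntheticConfig(n_applicants=10, stages=["a", "b", "c"], corr_matrix=bad)
        with pytest.raises(ValueError, match="positive definite"):
            generate_latent(cfg)


class TestApplySelection:
    def test_fraction_one_is_identity(self):
        cfg = SyntheticConfig(n_applicants=50, stages=["a", "b"], lag1=[0.5],
                              selection_stage="a", selected_fraction=1.0, seed=3)
        z = generate_latent(cfg)
        assert apply_selection(z, cfg).equals(z)

    def test_truncated_normal_moments(self):
        cfg = SyntheticConfig(n_applicants=200000, stages=["a", "b"], lag1=[0.5],
                              selection_stage="a", selected_fraction=0.4, seed=4)
        z = generate_latent(cfg)
        entrants = apply_selection(z, cfg)
        # top 40% of a standard normal: mean = phi(z_.6)/.4 ~ 1.0446
        cut = norm.ppf(0.6)
        expected_mean = norm.pdf(cut) / 0.4
        assert entrants["a"].mean() == pytest.approx(expected_mean, abs=0.02)
        assert entrants["a"].std() < z["a"].std()

    def test_range_restriction_attenuates_correlation(self):
        weaker = 0
        for seed in range(20):
            cfg = SyntheticConfig(n_applicants=3000, stages=["a", "b"], lag1=[0.6],
                                  selection_stage="a", selected_fraction=0.4, seed=seed)
            z = generate_latent(cfg)
            entrants = apply_selection(z, cfg)
            weaker += entrants["a"].corr(entrants["b"]) < z["a"].corr(z["b"])
        assert weaker >= 18

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            SyntheticConfig(n_applicants=10, stages=["a", "b"], lag1=[0.5],
                            selection_stage="a", selected_fraction=0.0)


class TestObserveStage:
    def test_ceiling_mass(self):
        rng = np.random.default_rng(5)
        latent = pd.Series(rng.standard_normal(100000))
        col, spec, truth = observe_stage(
            latent, StageObservation("ceiling", ceiling_quantile=0.375), "alevel", rng
        )
        at_ceiling = (col >= truth["censoring_point"]).mean()
        assert at_ceiling == pytest.approx(0.625, abs=0.01)
        assert spec.kind == "censored_continuous"

    def test_ordinal_proportions(self):
        rng = np.random.default_rng(6)
        latent = pd.Series(rng.standard_normal(100000))
        props = (0.067, 0.283, 0.533, 0.117)
        col, spec, truth = observe_stage(
            latent, StageObservation("ordinal", proportions=props), "outcome", rng
        )
        freq = col.value_counts(normalize=True).sort_index().to_numpy()
        assert freq == pytest.approx(props, abs=0.01)
        assert spec.n_categories == 4 and len(truth["thresholds"]) == 3

    def test_binary_prevalence(self):
        rng = np.random.default_rng(7)
        latent = pd.Series(rng.standard_normal(50000))
        col, spec, _ = observe_stage(
            latent, StageObservation("binary", prevalence=0.554), "register", rng
        )
        assert (col == 2.0).mean() == pytest.approx(0.554, abs=0.01)

    def test_noise_free_continuous_is_identity(self):
        rng = np.random.default_rng(8)
        latent = pd.Series(rng.standard_normal(100))
        col, spec, _ = observe_stage(latent, StageObservation(), "y1", rng)
        assert np.array_equal(col.to_numpy(), latent.to_numpy())

    def test_reliability_controls_noise_share(self):
        rng = np.random.default_rng(9)
        latent = pd.Series(rng.standard_normal(100000))
        col, _, _ = observe_stage(
            latent, StageObservation(reliability=0.8), "y1", rng
        )
        assert latent.corr(col) ** 2 == pytest.approx(0.8, abs=0.01)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            StageObservation("ordinal", proportions=(0.5, 0.3, 0.1))


class TestApplyUptake:
    def make(self, n, slope, intercept, seed=0):
        rng = np.random.default_rng(seed)
        latent = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        table = latent.copy()
        out = apply_uptake(table, latent, [Uptake("b", "a", intercept, slope)], rng)
        return latent, out

    def test_zero_slope_rate_matches_logistic_intercept(self):
        from scipy.special import expit

        _, out = self.make(50000, 0.0, -0.5)
        assert out["b_attempted"].mean() == pytest.approx(expit(-0.5), abs=0.01)

    def test_positive_slope_selects_stronger_students(self):
        for seed in range(5):
            latent, out = self.make(5000, 1.0, 0.0, seed)
            att = out["b_attempted"]
            assert latent.loc[att, "a"].mean() > latent.loc[~att, "a"].mean()

    def test_extreme_negative_intercept_masks_everything(self):
        _, out = self.make(200, 0.0, -50.0)
        assert out["b"].isna().all()

    def test_uptake_must_reference_earlier_stage(self):
        rng = np.random.default_rng(1)
        latent = pd.DataFrame({"a": rng.standard_normal(10), "b": rng.standard_normal(10)})
        with pytest.raises(ValueError, match="earlier"):
            apply_uptake(latent.copy(), latent, [Uptake("a", "b", 0.0, 1.0)], rng)


class TestGenerateCohort:
    def test_uclms_like_preset_contract(self):
        table, specs, truth = generate_cohort(uclms_like(seed=11))
        assert len(table) == 729
        ceil = truth.censoring_points["alevel"]
        assert (table["alevel"] >= ceil).mean() == pytest.approx(0.625, abs=0.04)
        assert table["mrcp_part1_attempted"].mean() == pytest.approx(0.346, abs=0.05)

    def test_degenerate_single_stage(self):
        cfg = SyntheticConfig(n_applicants=50, stages=["only"], lag1=[], seed=1)
        table, specs, truth = generate_cohort(cfg)
        assert list(table.columns) == ["only"] and truth.corr_matrix.shape == (1, 1)

    def test_identical_configs_identical_tables(self):
        a, _, _ = generate_cohort(cohort_1990_like(n_applicants=500, seed=21))
        b, _, _ = generate_cohort(cohort_1990_like(n_applicants=500, seed=21))
        assert a.equals(b)

    def test_truth_sufficient_for_recovery(self):
        table, specs, truth = generate_cohort(uclms_like(n_entrants=300, seed=31))
        # every estimator-facing fact is recorded
        assert truth.latent_corr("gcse", "alevel") == pytest.approx(0.7)
        assert specs["alevel"].ceiling == truth.censoring_points["alevel"]
        assert truth.selection_stage == "alevel"

    def test_censored_estimator_recovers_truth_from_generated_pair(self):
        """Round trip: generator output -> latent-correlation estimator."""
        from cohortpath.latentcorr import fit_latent_correlation
        from cohortpath.mcmc import McmcConfig

        cfg = SyntheticConfig(
            n_applicants=1500, stages=["a", "b"], lag1=[0.6],
            observation={"a": StageObservation("ceiling", ceiling_quantile=0.4)},
            seed=41,
        )
        table, specs, truth = generate_cohort(cfg)
        est = fit_latent_correlation(
            table["a"].to_numpy(), table["b"].to_numpy(),
            specs["a"], specs["b"], McmcConfig(seed=41),
        )
        assert est.rho == pytest.approx(0.6, abs=0.1)
        assert est.ci[0] - 0.05 < 0.6 < est.ci[1] + 0.05
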