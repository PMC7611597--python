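"""Design matrix, Laplace fit, MCMC oracle, DIC, screening, dispersion."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from epidemand import (BayesianPoissonModel, build_design, compute_dic,
                       default_priors, model_registry, overdispersion_check,
                       screen_covariate)
from epidemand.model import (FitError, ModelSpec, PriorSpec, deviance,
                             PoissonLaplaceResults)

from conftest import intercept_only_design, make_strata_frame, small_scenario


def _full_factor_frame(**cell_overrides):
    """One row per age x gender x ethnicity cell for one area, so that
    treatment coding has every level available."""
    cfg = small_scenario()
    rows = []
    for a in cfg.age_bands:
        for g in cfg.genders:
            for e in cfg.ethnic_groups:
                rows.append({"age_band": a, "gender": g, "ethnicity": e,
                             "cases": 1, "person_years": 1000.0})
    return make_strata_frame(rows)


class TestDesign:
    def test_reference_stratum_row_is_intercept_only(self, small_seed):
        spec = model_registry("linear")[4]
        design = build_design(small_seed.frame, spec)
        frame = small_seed.frame.loc[design.row_index]
        ref = ((frame["age_band"] == "16-17") & (frame["gender"] == "female")
               & (frame["ethnicity"] == "white_british")).to_numpy()
        i = np.argmax(ref)
        row = design.X[i].copy()
        # individual-term columns of the reference stratum are all zero
        n_cat = 1 + 10 + 1 + 10 + 8
        assert row[0] == 1.0
        assert np.all(row[1:n_cat] == 0.0)

    def test_model4_linear_deprivation_has_33_columns(self, small_seed):
        design = build_design(small_seed.frame, model_registry("linear")[4])
        assert design.n_params == 1 + 10 + 1 + 10 + 8 + 3 == 33

    def test_quadratic_deprivation_adds_one_column(self, small_seed):
        design = build_design(small_seed.frame, model_registry("quadratic")[4])
        assert design.n_params == 34
        assert "deprivation_sq" in design.columns

    def test_zero_person_year_strata_dropped(self):
        frame = _full_factor_frame()
        frame.loc[0, "person_years"] = 0.0
        frame.loc[0, "cases"] = 0
        design = build_design(frame, model_registry()[1])
        assert design.n_dropped_zero_py == 1
        assert len(design.y) == len(frame) - 1

    def test_unseen_level_rejected_at_transform(self, small_seed):
        design = build_design(small_seed.frame, model_registry()[4])
        probe = small_seed.frame.head(5).copy()
        probe.loc[probe.index[0], "ethnicity"] = "martian"
        with pytest.raises(ValueError, match="martian"):
            design.transform(probe)

    def test_missing_covariate_column_rejected(self, small_seed):
        design = build_design(small_seed.frame, model_registry()[4])
        with pytest.raises(ValueError, match="cannabis_prevalence"):
            design.transform(small_seed.frame.drop(columns=["cannabis_prevalence"]))

    def test_all_zero_exposure_rejected(self):
        frame = _full_factor_frame()
        frame["person_years"] = 0.0
        frame["cases"] = 0
        with pytest.raises(ValueError, match="zero person-years"):
            build_design(frame, model_registry()[1])

    def test_constant_covariate_rejected(self):
        frame = _full_factor_frame()  # single area -> constant covariates
        with pytest.raises(ValueError, match="constant"):
            build_design(frame, model_registry()[4])


class TestLaplaceFit:
    def test_intercept_only_mode_is_log_crude_rate(self):
        """100 cases on 10 000 person-years under a flat-ish prior: the
        posterior mode is the Poisson MLE log(0.01) = -4.6052."""
        design = intercept_only_design(np.array([60.0, 40.0]),
                                       np.array([6000.0, 4000.0]))
        model = BayesianPoissonModel(
            design, PriorSpec(intercept_sd=100.0))
        res = model.fit(n_draws=0)
        # the sd-100 prior pulls the mode toward 0 by ~5e-6
        assert res.params[0] == pytest.approx(np.log(0.01), abs=1e-4)

    def test_strong_prior_dominates_without_likelihood_information(self):
        """Zero observed cases everywhere: a tight prior pins its
        coefficient at the prior mean."""
        frame = _full_factor_frame()
        frame["cases"] = 0
        spec = model_registry("linear")[1]
        m_target = 0.7
        priors = PriorSpec(overrides={"gender[male]": (m_target, 0.01)})
        model = BayesianPoissonModel.from_dataframe(frame, spec, priors)
        res = model.fit(n_draws=0)
        i = res.columns.index("gender[male]")
        assert abs(res.params[i] - m_target) < 0.01

    def test_prior_dominance_limit(self, small_seed):
        """As every prior sd -> 0 the posterior mode -> prior mean."""
        spec = model_registry()[1]
        priors = PriorSpec(default_mean=0.2, default_sd=1e-4,
                           intercept_sd=10.0)
        model = BayesianPoissonModel.from_dataframe(small_seed.frame, spec,
                                                    priors)
        res = model.fit(n_draws=0)
        non_int = [i for i, c in enumerate(res.columns) if c != "intercept"]
        np.testing.assert_allclose(res.params[non_int], 0.2, atol=5e-3)

    def test_draw_covariance_matches_inverse_curvature(self):
        design = intercept_only_design(np.array([80.0, 30.0]),
                                       np.array([5000.0, 3000.0]))
        model = BayesianPoissonModel(design, PriorSpec())
        res = model.fit(n_draws=100_000, rng_seed=5, compute_dic_=False)
        emp = np.cov(res.draws.T).reshape(1, 1)
        np.testing.assert_allclose(emp, res.cov_params(), rtol=0.05)

    def test_reference_invariance_to_covariate_shift(self, small_seed):
        """Adding a constant to a continuous covariate before z-scoring
        leaves every relative risk unchanged."""
        spec = model_registry()[4]
        res1 = BayesianPoissonModel.from_dataframe(
            small_seed.frame, spec, default_priors()).fit(n_draws=200,
                                                          rng_seed=7,
                                                          compute_dic_=False)
        shifted = small_seed.frame.copy()
        shifted["social_fragmentation"] = shifted["social_fragmentation"] + 3.7
        res2 = BayesianPoissonModel.from_dataframe(
            shifted, spec, default_priors()).fit(n_draws=200, rng_seed=7,
                                                 compute_dic_=False)
        np.testing.assert_allclose(res1.params, res2.params, atol=1e-6)

    def test_collinear_columns_reported(self):
        frame = _full_factor_frame()
        frame2 = pd.concat([frame, frame], ignore_index=True)
        frame2["area_id"] = (["area_000"] * len(frame)
                             + ["area_001"] * len(frame))
        rng = np.random.default_rng(0)
        frame2["cases"] = rng.poisson(1.0, len(frame2))
        frame2.loc[frame2["area_id"] == "area_001", "deprivation"] = 1.0
        frame2.loc[frame2["area_id"] == "area_001", "inequality"] = 1.0
        spec = ModelSpec(9, ("deprivation", "inequality"), "linear")
        model = BayesianPoissonModel.from_dataframe(
            frame2, spec, PriorSpec(default_sd=1e6, intercept_sd=1e6))
        with pytest.raises(FitError, match="collinear"):
            model.fit(n_draws=0)


class TestDIC:
    def _fit_with_draws(self, design, draws):
        model = BayesianPoissonModel(design, PriorSpec())
        res = model.fit(n_draws=0)
        res.draws = draws
        return res

    def test_degenerate_draws_give_zero_pd(self):
        design = intercept_only_design(np.array([10.0, 5.0]),
                                       np.array([1000.0, 500.0]))
        draws = np.full((200, 1), -4.0)
        res = self._fit_with_draws(design, draws)
        dic = compute_dic(res, design)
        assert res.effective_parameters == pytest.approx(0.0, abs=1e-9)
        assert dic == pytest.approx(deviance(np.array([-4.0]), design))

    def test_hand_computed_two_stratum_example(self):
        """Three fixed draws on a 2-stratum design: DIC equals the direct
        formula evaluated with scalar arithmetic."""
        y = np.array([3.0, 7.0])
        py = np.array([100.0, 400.0])
        design = intercept_only_design(y, py)
        base = np.array([-3.6, -3.9, -4.2])
        draws = np.repeat(base, 34)[:, None]  # >=100 draws, same 3 values

        def dev(b):
            mu = py * np.exp(b)
            ll = (y * (b + np.log(py)) - mu - gammaln(y + 1)).sum()
            return -2 * ll

        dbar = np.mean([dev(b) for b in np.repeat(base, 34)])
        dhat = dev(np.repeat(base, 34).mean())
        expected = 2 * dbar - dhat
        res = self._fit_with_draws(design, draws)
        assert compute_dic(res, design) == pytest.approx(expected, rel=1e-12)

    def test_too_few_draws_rejected(self):
        design = intercept_only_design(np.array([3.0]), np.array([100.0]))
        res = self._fit_with_draws(design, np.zeros((10, 1)))
        with pytest.raises(ValueError, match="100"):
            compute_dic(res, design)

    def test_dic_prefers_generating_model(self):
        """Data with a real deprivation effect: the model including
        deprivation beats the individual-terms-only model in every
        replicate."""
        wins = 0
        reps = 5
        for s in range(reps):
            cfg = small_scenario(rng_seed=300 + s,
                                 expected_total_cases=1600.0,
                                 total_person_years=4_000_000.0)
            from epidemand import generate_seed_dataset
            ds = generate_seed_dataset(cfg)
            d1 = BayesianPoissonModel.from_dataframe(
                ds.frame, model_registry()[1], default_priors()).fit(
                    n_draws=300, rng_seed=s)
            d2 = BayesianPoissonModel.from_dataframe(
                ds.frame, model_registry()[2], default_priors()).fit(
                    n_draws=300, rng_seed=s)
            wins += d2.dic < d1.dic
        assert wins == reps


class TestRelativeRisks:
    def test_constant_draws_give_exact_rr(self):
        design = intercept_only_design(np.array([3.0]), np.array([100.0]))
        model = BayesianPoissonModel(design, PriorSpec())
        res = model.fit(n_draws=0)
        res.draws = np.full((50, 1), np.log(2.0))
        tab = res.relative_risks().set_index("coefficient")
        assert tab.loc["intercept", "rr"] == pytest.approx(2.0)
        assert tab.loc["intercept", "rr_lower"] == pytest.approx(2.0)
        assert tab.loc["intercept", "rr_upper"] == pytest.approx(2.0)

    def test_reference_categories_reported_as_unity(self, small_fit):
        tab = small_fit.relative_risks(include_reference=True)
        refs = tab[tab["reference"]]
        assert set(refs["coefficient"]) == {"age[16-17]", "gender[female]",
                                            "eth[white_british]"}
        assert (refs["rr"] == 1.0).all()

    def test_summary_renders(self, small_fit):
        text = small_fit.summary()
        assert "DIC" in text and "eth[black_caribbean]" in text


class TestScreening:
    def test_null_covariate_dropped_and_real_covariate_kept(self, small_seed):
        base = model_registry()[4]
        null = screen_covariate(small_seed.frame, base, "inequality",
                                n_draws=500, rng_seed=2)
        assert not null.keep
        assert null.rr_lower <= 1.0 <= null.rr_upper
        # cannabis is generated with RR 1.41/s.d.; screening from model 1
        base1 = model_registry()[1]
        keep = screen_covariate(small_seed.frame, base1,
                                "cannabis_prevalence", n_draws=500,
                                rng_seed=2)
        assert keep.keep and keep.rr_lower > 1.0

    def test_constant_covariate_rejected(self, small_seed):
        frame = small_seed.frame.copy()
        frame["inequality"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            screen_covariate(frame, model_registry()[4], "inequality")


def dense_scenario(seed):
    """Fewer, larger cells (mean counts well above 1) so the Pearson
    statistic has power to see extra-Poisson variation."""
    return small_scenario(
        n_areas=40, n_regions=8, n_ccgs=5, rng_seed=seed,
        age_bands=["16-17", "20-24", "30-34", "40-44", "50-54"],
        ethnic_groups=["white_british", "white_other", "black_caribbean",
                       "indian", "mixed"],
        true_coefficients={"age[20-24]": 0.4, "age[30-34]": -0.1,
                           "age[40-44]": -0.7, "age[50-54]": -1.1,
                           "gender[male]": 0.3,
                           "eth[black_caribbean]": 1.57,
                           "eth[white_other]": 0.26, "eth[indian]": 0.53,
                           "eth[mixed]": 0.83, "deprivation": 0.15,
                           "social_fragmentation": -0.08,
                           "cannabis_prevalence": 0.34},
        expected_total_cases=4000.0, total_person_years=2_000_000.0)


class TestOverdispersion:
    def test_correctly_specified_model_near_unity(self):
        hits = 0
        reps = 20
        for s in range(reps):
            from epidemand import generate_seed_dataset
            ds = generate_seed_dataset(dense_scenario(500 + s))
            r = overdispersion_check(ds.frame, model_registry()[4],
                                     compare_nb=False, rng_seed=s)
            hits += 0.8 <= r.statistic <= 1.2
            assert r.verdict == "no overdispersion"
        assert hits >= 0.9 * reps

    def test_gamma_mixed_rates_flagged_overdispersed(self):
        """Gamma-mixed Poisson rates (shape 0.5) force variance >> mean."""
        flagged = 0
        reps = 10
        for s in range(reps):
            cfg = dense_scenario(700 + s)
            from epidemand.simulate import expected_rates, _structure_frame
            rng = np.random.default_rng(700 + s)
            frame = _structure_frame(cfg, rng)
            lam, _ = expected_rates(cfg, frame)
            mix = rng.gamma(0.5, 2.0, len(lam))  # mean 1, variance 2
            frame["cases"] = rng.poisson(lam * mix)
            frame.loc[frame["person_years"] <= 0, "cases"] = 0
            r = overdispersion_check(frame, model_registry()[4],
                                     compare_nb=False, rng_seed=s)
            flagged += r.verdict == "overdispersed"
        assert flagged >= 0.9 * reps

    def test_negative_binomial_comparison_reported(self):
        from epidemand import generate_seed_dataset
        ds = generate_seed_dataset(dense_scenario(55))
        r = overdispersion_check(ds.frame, model_registry()[4],
                                 compare_nb=True, rng_seed=0)
        assert r.poisson_mle_loglike is not None
        if r.nb_loglike is not None:
            # equidispersed data: NB cannot beat Poisson by much
            assert r.nb_loglike <= r.poisson_mle_loglike + 2.0

    def test_two_cell_hand_formula(self):
        """Dispersion equals sum((obs-fit)^2/fit)/df for printed values."""
        y = np.array([12.0, 4.0])
        py = np.array([1000.0, 1000.0])
        design = intercept_only_design(y, py)
        model = BayesianPoissonModel(design, PriorSpec(intercept_sd=100.0))
        res = model.fit(n_draws=0)
        mu = res.fittedvalues()
        # sd-100 prior pulls the fit off the MLE by ~3e-5 relative
        np.testing.assert_allclose(mu, [8.0, 8.0], rtol=1e-3)
        stat = (((y - mu) ** 2) / mu).sum() / (2 - 1)
        assert stat == pytest.approx((16 + 16) / 8.0, rel=1e-3)


class TestMetropolisOracle:
    def test_zero_iterations_rejected(self):
        design = intercept_only_design(np.array([3.0]), np.array([100.0]))
        model = BayesianPoissonModel(design, PriorSpec())
        with pytest.raises(ValueError):
            model.fit_mcmc(n_draws=0)

    def test_intercept_only_agrees_with_laplace_mode(self):
        design = intercept_only_design(np.array([60.0, 40.0]),
                                       np.array([6000.0, 4000.0]))
        model = BayesianPoissonModel(design, PriorSpec(intercept_sd=100.0))
        lap = model.fit(n_draws=0)
        mcmc = model.fit_mcmc(n_draws=2000, burn=500, rng_seed=8)
        assert mcmc.usable
        mc_se = mcmc.draws[:, 0].std() / np.sqrt(200)  # generous ESS margin
        assert abs(mcmc.draws[:, 0].mean() - lap.params[0]) < 4 * mc_se + 0.01

    def test_oracle_equivalence_on_moderate_design(self):
        """Laplace and Metropolis posterior means agree within 0.05 on the
        log scale, and interval endpoints within 10% of interval width,
        for a <=40-coefficient design."""
        from epidemand import generate_seed_dataset
        ds = generate_seed_dataset(dense_scenario(42))
        model = BayesianPoissonModel.from_dataframe(
            ds.frame, model_registry()[4], default_priors())
        lap = model.fit(n_draws=4000, rng_seed=1, compute_dic_=False)
        mcmc = model.fit_mcmc(n_draws=12_000, burn=6000, rng_seed=1)
        assert mcmc.usable
        np.testing.assert_allclose(mcmc.draws.mean(axis=0),
                                   lap.draws.mean(axis=0), atol=0.05)
        lo_l, hi_l = np.quantile(lap.draws, [0.025, 0.975], axis=0)
        lo_m, hi_m = np.quantile(mcmc.draws, [0.025, 0.975], axis=0)
        width = hi_l - lo_l
        assert np.all(np.abs(lo_l - lo_m) < 0.1 * width + 0.01)
        assert np.all(np.abs(hi_l - hi_m) < 0.1 * width + 0.01)
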