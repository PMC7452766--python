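"""Design construction, Gibbs samplers, predictions, likelihoods, PSRF."""

import numpy as np
import pytest
from scipy.stats import norm, ortho_group

import rafspec
from rafspec.jsdm import (
    McmcConfig,
    ModelSpec,
    build_design,
    fit_abundance_lognormal,
    fit_hurdle,
    fit_pa_probit,
    pointwise_loglik,
    predict_occurrence,
    split_psrf,
)

from conftest import toy_sample_frame


class TestModelSpec:
    def test_names_round_trip(self):
        for name in ("m1", "m2", "m3"):
            assert ModelSpec.from_name(name).name == name

    def test_interaction_requires_host_term(self):
        with pytest.raises(ValueError):
            ModelSpec(include_host=False, include_host_elevation=True)


class TestDesign:
    @pytest.fixture(scope="class")
    def frame(self):
        return rafspec.generate_design(rafspec.DesignConfig(seed=0))

    @pytest.mark.parametrize("name,p", [("m1", 8), ("m2", 12), ("m3", 16)])
    def test_column_counts_five_hosts(self, frame, name, p):
        d = build_design(frame, ModelSpec.from_name(name))
        assert d.p == p

    def test_continuous_columns_standardized(self, frame):
        d = build_design(frame, ModelSpec.from_name("m1"))
        for col in ("elevation", "elevation_sq", "soil_ph", "log_seq_depth"):
            x = d.X[:, d.columns.index(col)]
            assert abs(x.mean()) < 1e-10
            assert x.std() == pytest.approx(1.0, abs=1e-10)

    def test_transform_reuses_training_standardization(self, frame):
        d = build_design(frame.iloc[:300], ModelSpec.from_name("m2"))
        X_new = d.transform(frame.iloc[300:])
        # new data standardized with training moments, so mean need not be 0
        assert X_new.shape == (len(frame) - 300, d.p)
        j = d.columns.index("elevation")
        expected = ((frame.iloc[300:]["elevation"] - d.center["elevation"])
                    / d.scale["elevation"])
        np.testing.assert_allclose(X_new[:, j], expected)

    def test_unseen_host_level_rejected(self):
        frame = toy_sample_frame(hosts=("A", "B"))
        d = build_design(frame, ModelSpec.from_name("m2"))
        other = toy_sample_frame(hosts=("A", "C"))
        with pytest.raises(ValueError, match="unseen host"):
            d.transform(other)


class TestProbitSampler:
    def test_intercept_only_recovers_probit_mle(self):
        rng = np.random.default_rng(1)
        n = 450
        y = (rng.random((n, 1)) < 0.5).astype(float)
        cfg = McmcConfig(n_chains=1, n_warmup=200, n_samples=200, thin=1,
                         n_factors=0, seed=2)
        d = fit_pa_probit(y, np.ones((n, 1)), np.zeros(n, int), 1, cfg)
        assert abs(d.beta.mean() - norm.ppf(y.mean())) < 0.15

    def test_known_beta_recovered_without_factors(self):
        rng = np.random.default_rng(3)
        n = 600
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        beta_true = np.array([[0.3, 1.0, -0.8], [-0.5, 0.0, 1.2]])
        y = ((X @ beta_true.T + rng.standard_normal((n, 2))) > 0).astype(float)
        cfg = McmcConfig(n_chains=1, n_warmup=300, n_samples=300, thin=1,
                         n_factors=0, seed=4)
        d = fit_pa_probit(y, X, np.zeros(n, int), 1, cfg)
        np.testing.assert_allclose(d.beta.mean(axis=0), beta_true, atol=0.25)

    def test_degenerate_column_warns_but_fits(self):
        y = np.column_stack([np.ones(50), np.zeros(50),
                             (np.arange(50) % 2).astype(float)])
        cfg = McmcConfig(n_chains=1, n_warmup=50, n_samples=50, thin=1,
                         n_factors=0, seed=0)
        with pytest.warns(UserWarning, match="all-absent or all-present"):
            d = fit_pa_probit(y, np.ones((50, 1)), np.zeros(50, int), 1, cfg)
        assert d.flags["degenerate_columns"] == [0, 1]

    def test_depends_only_on_presence_not_counts(self, uniform_dataset,
                                                 quick_mcmc):
        # hurdle separation: the occurrence posterior ignores count magnitudes
        ds, _ = uniform_dataset
        fit_a = fit_hurdle(ds, ModelSpec.from_name("m1"), quick_mcmc,
                           parts=("pa",))
        doubled = rafspec.CommunityDataset(
            rafspec.OtuTable(ds.table.sample_ids, ds.table.otu_ids,
                             ds.table.counts * 2),
            ds.samples, ds.guilds)
        fit_b = fit_hurdle(doubled, ModelSpec.from_name("m1"), quick_mcmc,
                           parts=("pa",))
        np.testing.assert_array_equal(fit_a.pa.beta, fit_b.pa.beta)


class TestAbundanceSampler:
    def test_noiseless_regression_recovered(self):
        rng = np.random.default_rng(5)
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta_true = np.array([[2.0, 1.0], [3.0, -0.5]])
        logY = X @ beta_true.T + 0.01 * rng.standard_normal((n, 2))
        cfg = McmcConfig(n_chains=1, n_warmup=200, n_samples=200, thin=1,
                         n_factors=0, seed=6)
        d = fit_abundance_lognormal(logY, np.ones((n, 2), bool), X,
                                    np.zeros(n, int), 1, cfg)
        np.testing.assert_allclose(d.beta.mean(axis=0), beta_true, atol=1e-2)

    def test_residual_sd_recovered(self):
        rng = np.random.default_rng(7)
        n = 400
        X = np.ones((n, 1))
        logY = 2.0 + 0.5 * rng.standard_normal((n, 1))
        cfg = McmcConfig(n_chains=1, n_warmup=200, n_samples=200, thin=1,
                         n_factors=0, seed=8)
        d = fit_abundance_lognormal(logY, np.ones((n, 1), bool), X,
                                    np.zeros(n, int), 1, cfg)
        assert 0.4 < d.sigma.mean() < 0.6

    def test_never_present_otu_returns_prior(self):
        rng = np.random.default_rng(9)
        n = 100
        X = np.ones((n, 1))
        present = np.zeros((n, 1), bool)
        cfg = McmcConfig(n_chains=1, n_warmup=100, n_samples=400, thin=1,
                         n_factors=0, seed=10)
        d = fit_abundance_lognormal(np.zeros((n, 1)), present, X,
                                    np.zeros(n, int), 1, cfg)
        assert d.flags["low_information"] == [0]
        # posterior equals the N(0, 25) prior within MC error
        assert abs(d.beta.mean()) < 1.0
        assert 4.0 < d.beta.std() < 6.0


class TestHurdleFit:
    def test_determinism_same_seed(self, uniform_dataset, quick_mcmc):
        ds, _ = uniform_dataset
        a = fit_hurdle(ds, ModelSpec.from_name("m2"), quick_mcmc)
        b = fit_hurdle(ds, ModelSpec.from_name("m2"), quick_mcmc)
        np.testing.assert_array_equal(a.pa.beta, b.pa.beta)
        np.testing.assert_array_equal(a.abund.sigma, b.abund.sigma)

    def test_single_otu_rejected(self, uniform_dataset, quick_mcmc):
        ds, _ = uniform_dataset
        one = rafspec.CommunityDataset(
            ds.table.select_otus(ds.table.otu_ids[:1]), ds.samples, ds.guilds)
        with pytest.raises(ValueError, match="at least 2 OTUs"):
            fit_hurdle(one, ModelSpec.from_name("m2"), quick_mcmc)

    def test_m1_converges_on_null_data(self):
        # full sampling design, prevalence-filtered, as in actual use
        ds, _ = rafspec.simulate_scenario("none", n_otus=20, seed=11)
        ds = rafspec.CommunityDataset(
            rafspec.filter_by_prevalence(ds.table, 0.05),
            ds.samples, ds.guilds)
        cfg = McmcConfig(n_chains=2, n_warmup=1000, n_samples=500, thin=2,
                         n_factors=2, seed=3)
        fit = fit_hurdle(ds, ModelSpec.from_name("m1"), cfg, parts=("pa",))
        assert fit.convergence["pa"]["max_psrf_beta"] < 1.1
        assert fit.convergence["pa"]["median_psrf_beta"] < 1.05


class TestPrediction:
    def test_null_model_predicts_half(self, uniform_dataset, quick_mcmc):
        ds, _ = uniform_dataset
        fit = fit_hurdle(ds, ModelSpec.from_name("m1"), quick_mcmc,
                         parts=("pa",))
        fit.pa.beta[:] = 0.0
        fit.pa.loadings[:] = 0.0
        probs = predict_occurrence(fit, ds.samples)
        np.testing.assert_allclose(probs, 0.5)

    def test_probability_monotone_in_linear_predictor(self, uniform_m2_fit,
                                                      uniform_dataset):
        ds, _ = uniform_dataset
        fit = uniform_m2_fit
        base = predict_occurrence(fit, ds.samples).mean(axis=0)
        fit_shift = rafspec.HurdleFit(
            fit.spec, fit.design, fit.pa, fit.abund, fit.config,
            fit.location_ids, fit.otu_ids)
        shifted = fit_shift.pa.beta.copy()
        shifted[:, :, 0] += 2.0  # raise every intercept
        fit_shift.pa = rafspec.jsdm.PosteriorDraws(
            shifted, fit.pa.loadings, fit.pa.factors, None,
            fit.pa.n_chains, fit.pa.n_per_chain, fit.pa.columns,
            fit.pa.location_ids)
        assert (fit.design.X is not None)
        higher = predict_occurrence(fit_shift, ds.samples).mean(axis=0)
        assert (higher >= base - 1e-12).all()

    def test_marginal_equals_conditional_when_loadings_zero(
            self, uniform_dataset, quick_mcmc):
        ds, _ = uniform_dataset
        fit = fit_hurdle(ds, ModelSpec.from_name("m1"), quick_mcmc,
                         parts=("pa",))
        fit.pa.loadings[:] = 0.0
        cond = predict_occurrence(fit, ds.samples, use_location_effect=True)
        marg = predict_occurrence(fit, ds.samples, use_location_effect=False)
        np.testing.assert_allclose(cond, marg, atol=1e-12)

    def test_unknown_location_conditional_rejected(self, uniform_m2_fit,
                                                   uniform_dataset):
        ds, _ = uniform_dataset
        frame = ds.samples.copy()
        frame["location_id"] = frame["location_id"].cat.add_categories(["LX"])
        frame.loc[frame.index[0], "location_id"] = "LX"
        with pytest.raises(ValueError, match="unknown location"):
            predict_occurrence(uniform_m2_fit, frame,
                               use_location_effect=True)

    def test_rotation_invariance_of_predictions(self, uniform_m2_fit,
                                                uniform_dataset):
        # loadings/factors are only identified up to rotation: predictions
        # must be invariant under (Lambda, eta) -> (Lambda Q, eta Q)
        ds, _ = uniform_dataset
        fit = uniform_m2_fit
        base = predict_occurrence(fit, ds.samples)
        Q = ortho_group.rvs(fit.config.n_factors, random_state=0)
        rotated = rafspec.jsdm.PosteriorDraws(
            fit.pa.beta, fit.pa.loadings @ Q, fit.pa.factors @ Q, None,
            fit.pa.n_chains, fit.pa.n_per_chain, fit.pa.columns,
            fit.pa.location_ids)
        fit_rot = rafspec.HurdleFit(
            fit.spec, fit.design, rotated, fit.abund, fit.config,
            fit.location_ids, fit.otu_ids)
        np.testing.assert_allclose(
            predict_occurrence(fit_rot, ds.samples), base, atol=1e-10)


class TestPointwiseLoglik:
    def test_closed_form_cells(self, uniform_dataset, quick_mcmc):
        ds, _ = uniform_dataset
        fit = fit_hurdle(ds, ModelSpec.from_name("m1"), quick_mcmc)
        # force known parameters: p = 0.5 everywhere, sigma = 1, mu = 0
        fit.pa.beta[:] = 0.0
        fit.pa.loadings[:] = 0.0
        fit.abund.beta[:] = 0.0
        fit.abund.loadings[:] = 0.0
        fit.abund.sigma[:] = 1.0
        ll = pointwise_loglik(fit, ds)
        np.testing.assert_allclose(ll["pa"], np.log(0.5), atol=1e-12)
        # abundance density at residual r: -0.5 log(2 pi) - r^2 / 2
        present = ds.table.counts > 0
        r = np.log(ds.table.counts[present])
        expected = -0.5 * np.log(2 * np.pi) - 0.5 * r**2
        np.testing.assert_allclose(ll["abund"][0], expected, atol=1e-12)

    def test_matches_direct_density_evaluation(self, uniform_m2_fit,
                                               uniform_dataset):
        ds, _ = uniform_dataset
        fit = uniform_m2_fit
        ll = pointwise_loglik(fit, ds)
        probs = predict_occurrence(fit, ds.samples)
        y = (ds.table.counts > 0).ravel()
        rng = np.random.default_rng(0)
        for cell in rng.integers(0, ll["pa"].shape[1], 10):
            p = probs[:, cell // ds.n_otus, cell % ds.n_otus]
            direct = np.where(y[cell], np.log(p), np.log1p(-p))
            np.testing.assert_allclose(ll["pa"][:, cell], direct, atol=1e-10)


class TestPsrf:
    def test_identical_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal((1, 500, 3))
        rhat = split_psrf(np.concatenate([chain, chain]))
        assert np.all(rhat < 1.05)

    def test_constant_chains_report_one(self):
        chains = np.ones((2, 100, 2))
        np.testing.assert_array_equal(split_psrf(chains), 1.0)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((1, 300, 1))
        b = rng.standard_normal((1, 300, 1)) + 5.0
        assert split_psrf(np.concatenate([a, b]))[0] > 1.2

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            split_psrf(np.zeros((1, 100, 1)))

    def test_agrees_with_arviz_on_stationary_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 400))
        mine = split_psrf(chains[:, :, None])[0]
        theirs = float(az.rhat(az.convert_to_dataset(chains[:, :, None]))
                       .to_array().values.ravel()[0])
        assert mine == pytest.approx(theirs, abs=0.05)
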