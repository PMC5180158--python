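"""Bayesian mass-balance mixing model: likelihood oracle checks,
sampler validation against closed forms, suite batching, averaging."""

import numpy as np
import pytest
from scipy import stats

from isodiet import (
    ConfigurationError,
    DiscriminationFactor,
    IsotopeMeasurement,
    MCMCSettings,
    MixingConfig,
    SourceSpec,
    average_models,
    corrected_source,
    log_likelihood,
    run_model_suite,
    sample_posterior,
)


def _consumer(d13c, d15n, i=0):
    return IsotopeMeasurement(f"c{i}", "consumer", d13C=d13c, d15N=d15n)


def _two_source_config(consumers, mcmc=None, zoo=None, meso=None, dtdf=None,
                       upper=10.0):
    zoo = zoo or SourceSpec("zoo", -19.7, 1.0, 7.8, 1.0)
    meso = meso or SourceSpec("meso", -17.6, 0.8, 6.2, 1.5)
    dtdf = dtdf or DiscriminationFactor(0.9, 0.33, 2.29, 0.22)
    return MixingConfig(
        sources=(zoo, meso), dtdf=dtdf, consumers=tuple(consumers),
        mcmc=mcmc or MCMCSettings(chains=2, iterations=2000, burn_in=400, seed=5),
        residual_sd_prior_upper=upper,
    )


class TestCorrectedSource:
    def test_mean_shift(self):
        src = SourceSpec("meso", -17.6, 0.8, 6.2, 1.5)
        dtdf = DiscriminationFactor(0.9, 0.33, 2.29, 0.22)
        mean, var = corrected_source(src, dtdf)
        assert mean[1] == pytest.approx(8.49)
        assert var[0] == pytest.approx(0.7489)

    def test_zero_dtdf_leaves_source_unchanged(self):
        src = SourceSpec("zoo", -20.5, 0.6, 7.8, 1.0)
        mean, var = corrected_source(src, DiscriminationFactor(0, 0, 0, 0))
        np.testing.assert_allclose(mean, src.means)
        np.testing.assert_allclose(var, src.sds**2)


class TestLogLikelihood:
    def test_matches_termwise_normal_density(self):
        """Brute-force oracle: per-isotope scipy normal logpdf, summed."""
        config = _two_source_config([_consumer(-16.8, 10.6)])
        p = np.array([0.3, 0.7])
        eps = np.array([0.5, 1.2])
        mu = np.array([corrected_source(s, config.dtdf)[0] for s in config.sources])
        var = np.array([corrected_source(s, config.dtdf)[1] for s in config.sources])
        expected = 0.0
        for j, y in enumerate([-16.8, 10.6]):
            m = (p * mu[:, j]).sum()
            s2 = (p**2 * var[:, j]).sum() + eps[j] ** 2
            expected += stats.norm.logpdf(y, m, np.sqrt(s2))
        assert log_likelihood(p, eps, config) == pytest.approx(expected, rel=1e-12)

    def test_identical_dispersionless_sources_make_likelihood_constant_in_p(self):
        """With identical corrected sources the mixture mean is constant
        in p; with zero source/DTDF dispersion the p^2-weighted variance
        term drops too, so the whole likelihood is flat in p."""
        src = SourceSpec("a", -18.0, 0.0, 8.0, 0.0)
        src2 = SourceSpec("b", -18.0, 0.0, 8.0, 0.0)
        config = MixingConfig(
            sources=(src, src2),
            dtdf=DiscriminationFactor(1.0, 0.0, 2.0, 0.0),
            consumers=(_consumer(-16.5, 10.0),),
        )
        vals = [
            log_likelihood([w, 1 - w], [0.5, 0.5], config)
            for w in (0.0, 0.25, 0.5, 0.9)
        ]
        assert np.ptp(vals) < 1e-10

    def test_identical_sources_symmetric_under_proportion_swap(self):
        src = SourceSpec("a", -18.0, 0.7, 8.0, 1.0)
        src2 = SourceSpec("b", -18.0, 0.7, 8.0, 1.0)
        config = MixingConfig(
            sources=(src, src2),
            dtdf=DiscriminationFactor(1.0, 0.3, 2.0, 0.2),
            consumers=(_consumer(-16.5, 10.0),),
        )
        for w in (0.1, 0.3, 0.45):
            assert log_likelihood([w, 1 - w], [0.5, 0.5], config) == (
                pytest.approx(log_likelihood([1 - w, w], [0.5, 0.5], config),
                              rel=1e-12)
            )

    def test_maximized_at_pure_diet_when_consumer_sits_on_source(self):
        """Grid search over the simplex finds the argmax at p = (1, 0)."""
        zoo = SourceSpec("zoo", -20.0, 1e-4, 8.0, 1e-4)
        meso = SourceSpec("meso", -16.0, 1e-4, 6.0, 1e-4)
        dtdf = DiscriminationFactor(0, 1e-4, 0, 1e-4)
        config = MixingConfig(sources=(zoo, meso), dtdf=dtdf,
                              consumers=(_consumer(-20.0, 8.0),))
        grid = np.linspace(0, 1, 101)
        lls = [log_likelihood([w, 1 - w], [1e-3, 1e-3], config) for w in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(1.0)

    def test_off_simplex_rejected(self):
        config = _two_source_config([_consumer(-16.8, 10.6)])
        with pytest.raises(ValueError):
            log_likelihood([0.6, 0.6], [1.0, 1.0], config)
        with pytest.raises(ValueError):
            log_likelihood([-0.2, 1.2], [1.0, 1.0], config)


class TestSamplePosterior:
    def test_symmetric_sources_give_half_half(self):
        """Two sources placed symmetrically about the consumer mean."""
        a = SourceSpec("a", -18.0, 1.0, 8.0, 1.0)
        b = SourceSpec("b", -14.0, 1.0, 12.0, 1.0)
        config = MixingConfig(
            sources=(a, b), dtdf=DiscriminationFactor(0, 0, 0, 0),
            consumers=tuple(_consumer(-16.0, 10.0, i) for i in range(30)),
            mcmc=MCMCSettings(chains=2, iterations=4000, burn_in=500, seed=11),
        )
        summary = sample_posterior(config)
        np.testing.assert_allclose(summary.means, [0.5, 0.5], atol=0.05)

    def test_deterministic_under_fixed_seed(self, fast_mcmc):
        config = _two_source_config([_consumer(-16.8, 10.6, i) for i in range(10)],
                                    mcmc=fast_mcmc)
        s1 = sample_posterior(config)
        s2 = sample_posterior(config)
        np.testing.assert_array_equal(s1.draws_p, s2.draws_p)
        np.testing.assert_array_equal(s1.draws_eps, s2.draws_eps)

    def test_draws_stay_on_simplex(self, fast_mcmc):
        config = _two_source_config([_consumer(-16.8, 10.6, i) for i in range(10)],
                                    mcmc=fast_mcmc)
        summary = sample_posterior(config)
        assert np.all(summary.draws_p >= 0)
        np.testing.assert_allclose(summary.draws_p.sum(axis=1), 1.0, atol=1e-12)
        # quantiles monotone, means on [0, 1]
        assert np.all(np.diff(summary.quantiles, axis=1) >= 0)
        assert np.all((summary.means >= 0) & (summary.means <= 1))

    def test_prior_only_recovers_dirichlet_moments(self):
        """With the likelihood disabled the sampler must reproduce the
        symmetric Dirichlet(1) prior: mean 1/K, var (K-1)/(K^2 (K+1))."""
        for k in (2, 3):
            sources = tuple(
                SourceSpec(f"s{i}", -20.0 + i, 1.0, 7.0 + i, 1.0) for i in range(k)
            )
            config = MixingConfig(
                sources=sources, dtdf=DiscriminationFactor(0, 0, 0, 0),
                consumers=(_consumer(-16.0, 10.0),),
                mcmc=MCMCSettings(chains=2, iterations=12000, burn_in=1000, seed=3),
            )
            summary = sample_posterior(config, prior_only=True)
            np.testing.assert_allclose(summary.means, 1 / k, atol=0.02)
            np.testing.assert_allclose(
                summary.draws_p.var(axis=0),
                (k - 1) / (k**2 * (k + 1)),
                atol=0.015,
            )

    def test_zero_variance_oracle_matches_linear_mass_balance(self):
        """With all SDs ~ 0 the posterior must invert the 2x2 system."""
        zoo = SourceSpec("zoo", -20.0, 1e-4, 8.0, 1e-4)
        meso = SourceSpec("meso", -16.0, 1e-4, 6.0, 1e-4)
        dtdf = DiscriminationFactor(0, 1e-4, 0, 1e-4)
        p_true = 0.35
        y = (p_true * np.array([-20.0, 8.0]) + (1 - p_true) * np.array([-16.0, 6.0]))
        config = MixingConfig(
            sources=(zoo, meso), dtdf=dtdf,
            consumers=(_consumer(*y),),
            mcmc=MCMCSettings(chains=2, iterations=6000, burn_in=1000, seed=9),
            residual_sd_prior_upper=1e-3,
        )
        summary = sample_posterior(config)
        # exact solution of the mass-balance equations
        a = np.array([[-20.0, -16.0], [8.0, 6.0], [1.0, 1.0]])
        exact = np.linalg.lstsq(a, np.array([y[0], y[1], 1.0]), rcond=None)[0]
        np.testing.assert_allclose(summary.means, exact, atol=0.01)

    def test_translation_equivariance(self, fast_mcmc):
        """Shifting sources and consumers together leaves p unchanged."""
        consumers = [_consumer(-16.8 + 0.1 * i, 10.6 - 0.05 * i, i)
                     for i in range(20)]
        base = _two_source_config(consumers, mcmc=fast_mcmc)
        shift = 5.0
        shifted = MixingConfig(
            sources=tuple(
                SourceSpec(s.name, s.mean_d13C + shift, s.sd_d13C,
                           s.mean_d15N + shift, s.sd_d15N)
                for s in base.sources
            ),
            dtdf=base.dtdf,
            consumers=tuple(
                _consumer(c.d13C + shift, c.d15N + shift, i)
                for i, c in enumerate(consumers)
            ),
            mcmc=fast_mcmc,
        )
        s1 = sample_posterior(base)
        s2 = sample_posterior(shifted)
        np.testing.assert_allclose(s1.means, s2.means, atol=0.03)

    def test_diagnostics_reported(self, fast_mcmc):
        config = _two_source_config([_consumer(-16.8, 10.6, i) for i in range(10)],
                                    mcmc=fast_mcmc)
        summary = sample_posterior(config)
        assert set(summary.rhat) == set(summary.ess)
        assert all(np.isfinite(v) for v in summary.rhat.values())
        assert isinstance(summary.converged, bool)


class TestConfigValidation:
    def test_single_source_rejected(self):
        with pytest.raises(ConfigurationError):
            MixingConfig(
                sources=(SourceSpec("only", -19.7, 1.0, 7.8, 1.0),),
                dtdf=DiscriminationFactor(0.9, 0.33, 2.29, 0.22),
                consumers=(_consumer(-16.8, 10.6),),
            )

    def test_too_many_sources_rejected(self):
        sources = tuple(
            SourceSpec(f"s{i}", -20.0 + i, 1.0, 7.0, 1.0) for i in range(4)
        )
        with pytest.raises(ConfigurationError):
            MixingConfig(sources=sources,
                         dtdf=DiscriminationFactor(0, 0, 0, 0),
                         consumers=(_consumer(-16.8, 10.6),))

    def test_no_consumers_rejected(self):
        with pytest.raises(ConfigurationError):
            MixingConfig(
                sources=(SourceSpec("a", -19.7, 1.0, 7.8, 1.0),
                         SourceSpec("b", -17.6, 0.8, 6.2, 1.5)),
                dtdf=DiscriminationFactor(0.9, 0.33, 2.29, 0.22),
                consumers=(),
            )


class TestModelSuite:
    def test_missing_variant_rejected(self, paper_sources, paper_dtdfs,
                                      consumers75, fast_mcmc):
        with pytest.raises(ConfigurationError):
            run_model_suite(consumers75,
                            {"bulk": paper_sources["bulk"]},
                            paper_dtdfs, mcmc=fast_mcmc)
        with pytest.raises(ConfigurationError):
            run_model_suite(consumers75, paper_sources,
                            {"large_shark": paper_dtdfs["large_shark"]},
                            mcmc=fast_mcmc)

    def test_labels_and_majority_mesopelagic(self, paper_sources, paper_dtdfs,
                                             consumers75, fast_mcmc):
        summaries = run_model_suite(consumers75, paper_sources, paper_dtdfs,
                                    mcmc=fast_mcmc)
        assert [s.label for s in summaries] == [
            "Model 1", "Model 2", "Model 3", "Model 4"
        ]
        meso = [s.means[1] for s in summaries]
        assert all(m > 0.5 for m in meso)
        surface = [s.means[0] for s in summaries]
        assert int(np.argmax(surface)) == 2  # Model 3 maximizes surface

    def test_identical_variants_give_identical_distributions(
            self, paper_dtdfs, consumers75, fast_mcmc):
        one = {
            "lipid_normalized": [SourceSpec("zoo", -19.7, 1.0, 7.8, 1.0),
                                 SourceSpec("meso", -17.6, 0.8, 6.2, 1.5)],
        }
        one["bulk"] = one["lipid_normalized"]
        same_dtdf = {"large_shark": paper_dtdfs["large_shark"],
                     "leopard_shark": paper_dtdfs["large_shark"]}
        summaries = run_model_suite(consumers75, one, same_dtdf, mcmc=fast_mcmc)
        means = np.array([s.means for s in summaries])
        assert np.ptp(means, axis=0).max() < 0.05


class TestAverageModels:
    def test_table_average_and_sd(self):
        """The across-model mean/SD arithmetic on four posterior means."""
        surface = [0.21, 0.12, 0.43, 0.33]
        summaries = []
        for label, s in zip(("Model 1", "Model 2", "Model 3", "Model 4"), surface):
            summaries.append(_stub_summary(label, [s, 1 - s]))
        avg = average_models(summaries)
        assert avg["surface"][0] == pytest.approx(0.2725)
        assert avg["surface"][1] == pytest.approx(0.1358, abs=5e-4)
        assert avg["meso"][0] == pytest.approx(0.7275)

    def test_identical_summaries_average_to_themselves(self):
        summaries = [_stub_summary(f"M{i}", [0.3, 0.7]) for i in range(4)]
        avg = average_models(summaries)
        assert avg["surface"] == (pytest.approx(0.3), pytest.approx(0.0))

    def test_mismatched_source_names_rejected(self):
        a = _stub_summary("M1", [0.3, 0.7])
        b = _stub_summary("M2", [0.3, 0.7], names=("x", "y"))
        with pytest.raises(ConfigurationError):
            average_models([a, b])


def _stub_summary(label, means, names=("surface", "meso")):
    from isodiet.mixing_model import PosteriorSummary

    means = np.asarray(means, dtype=float)
    return PosteriorSummary(
        label=label, source_names=list(names), means=means,
        sds=np.zeros_like(means),
        quantiles=np.tile(means[:, None], (1, 5)),
        residual_sd_mean=np.zeros(2), residual_sd_sd=np.zeros(2),
        rhat={}, ess={}, converged=True,
        draws_p=means[None, :], draws_eps=np.zeros((1, 2)),
    )
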