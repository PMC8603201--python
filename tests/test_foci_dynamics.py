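"""Foci-model checks: beta-binomial marginal vs quadrature, degenerate
data, posterior monotonicity, expected counts, PPC and PSIS-LOO."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from fluxfoci import (FociSimConfig, expected_foci, fit_foci_model,
                      loo_compare, marginal_foci_logpmf, ppc_foci,
                      simulate_foci_dataset)
from fluxfoci._mcmc import SamplerSettings
from fluxfoci.foci_dynamics import importance_ratios


class TestMarginalLikelihood:
    def quadrature(self, k, n, p, phi):
        a, b = phi * p, phi * (1 - p)
        val, _ = integrate.quad(
            lambda q: stats.binom.pmf(k, n, q) * stats.beta.pdf(q, a, b),
            0.0, 1.0, limit=200)
        return val

    @pytest.mark.parametrize("k,n,p,phi", [
        (0, 10, 0.05, 20.0), (3, 10, 0.2, 5.0), (10, 10, 0.9, 2.0),
        (7, 50, 0.1, 100.0), (25, 50, 0.5, 0.5),
    ])
    def test_matches_numerical_integration(self, k, n, p, phi):
        ours = np.exp(marginal_foci_logpmf(k, n, p, phi))
        ref = self.quadrature(k, n, p, phi)
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_matches_scipy_betabinom(self):
        ref = stats.betabinom.logpmf(4, 30, 3.0, 17.0)
        ours = marginal_foci_logpmf(4, 30, 3.0 / 20.0, 20.0)
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_sums_to_one_over_support(self):
        n, p, phi = 25, 0.3, 8.0
        total = np.exp(marginal_foci_logpmf(np.arange(n + 1), n, p, phi)).sum()
        assert total == pytest.approx(1.0, rel=1e-10)


class TestHierarchicalFit:
    def test_all_zero_time_point_gives_tiny_p(self):
        cfg = FociSimConfig(p_curves={"z": (0.0, 0.02)}, times=(0.0, 0.5),
                            n_replicates=3, nuclei_per_replicate=40, seed=2)
        df = simulate_foci_dataset(cfg)
        post = fit_foci_model(df, SamplerSettings(steps=1000, seed=3))
        assert float(np.median(post.p_t[:, 0])) < 1e-3

    def test_single_replicate_refused_with_guidance(self):
        cfg = FociSimConfig(p_curves={"a": (0.01, 0.02)}, times=(0.0, 0.5),
                            n_replicates=1, nuclei_per_replicate=10, seed=1)
        df = simulate_foci_dataset(cfg)
        with pytest.raises(ValueError, match="pooled"):
            fit_foci_model(df)

    def test_monotone_decreasing_density_gives_monotone_medians(self, clean_fit):
        # truth declines after the 0.5 h peak; check the repair segment
        med = np.median(clean_fit.p_t, axis=0)
        assert np.all(np.diff(med[1:]) < 0)

    def test_draws_lie_in_unit_interval_and_v_below_bound(self, clean_fit):
        assert np.all((clean_fit.p_t > 0) & (clean_fit.p_t < 1))
        bound = clean_fit.p_t * (1 - clean_fit.p_t)
        assert np.all((clean_fit.v_t > 0) & (clean_fit.v_t < bound))

    def test_chain_order_invariance(self, clean_fit):
        fwd = np.median(clean_fit.p_t_chains.reshape(-1, 5), axis=0)
        rev = np.median(clean_fit.p_t_chains[::-1].reshape(-1, 5), axis=0)
        np.testing.assert_allclose(fwd, rev)

    def test_log_likelihood_finite(self, clean_fit):
        assert np.all(np.isfinite(clean_fit.log_lik))

    def test_determinism_under_seed(self):
        cfg = FociSimConfig(p_curves={"a": (0.01, 0.02)}, times=(0.0, 0.5),
                            n_replicates=2, nuclei_per_replicate=15, seed=5)
        df = simulate_foci_dataset(cfg)
        s = SamplerSettings(steps=300, seed=17)
        a = fit_foci_model(df, s)
        b = fit_foci_model(df, s)
        np.testing.assert_array_equal(a.p_t, b.p_t)


class TestExpectedFoci:
    def test_unit_area_equals_p_summary(self, clean_fit):
        one = expected_foci(clean_fit, 1.0)
        np.testing.assert_allclose(one["median"],
                                   np.median(clean_fit.p_t, axis=0))

    def test_linear_in_area(self, clean_fit):
        one = expected_foci(clean_fit, 300.0)
        two = expected_foci(clean_fit, 600.0)
        np.testing.assert_allclose(two["median"], 2 * one["median"])
        np.testing.assert_allclose(two["cri95_hi"], 2 * one["cri95_hi"])

    def test_matches_monte_carlo_beta_binomial_mean(self, rng):
        # E[k] for beta-binomial is n*p independent of dispersion
        n, p, phi = 400, 0.02, 150.0
        draws = rng.binomial(n, rng.beta(phi * p, phi * (1 - p), size=200_000))
        assert draws.mean() == pytest.approx(n * p, rel=0.02)


class TestPPC:
    def test_self_generated_data_calibrated(self, clean_fit):
        rep = ppc_foci(clean_fit, seed=1)
        mean_rows = rep[rep["statistic"].str.startswith("mean_count")]
        ok = ((mean_rows["tail_prob"] >= 0.05)
              & (mean_rows["tail_prob"] <= 0.95)).sum()
        assert ok >= len(mean_rows) - 1

    def test_doubled_counts_flagged(self, clean_fit):
        doubled = clean_fit.obs.assign(
            foci_count=np.minimum(clean_fit.obs["foci_count"] * 4 + 2,
                                  clean_fit.obs["area_units"]))
        rep = ppc_foci(clean_fit, records=doubled, seed=1)
        mean_rows = rep[rep["statistic"].str.startswith("mean_count")]
        assert (mean_rows["tail_prob"] < 0.01).any()

    def test_report_has_row_per_statistic(self, clean_fit):
        rep = ppc_foci(clean_fit, seed=2)
        assert rep["statistic"].is_unique
        assert (rep["statistic"] == "max_count").any()


class TestLoo:
    def test_identical_fits_give_zero_difference(self, clean_fit):
        cmp = loo_compare(clean_fit, clean_fit)
        assert cmp.elpd_diff == 0.0
        assert cmp.preferred is None

    def test_mismatched_records_rejected(self, clean_fit):
        cfg = FociSimConfig(p_curves={"lineA": (0.01, 0.02)},
                            times=(0.0, 0.5), nuclei_per_replicate=10, seed=9)
        other = fit_foci_model(simulate_foci_dataset(cfg),
                               SamplerSettings(steps=300, seed=1))
        with pytest.raises(ValueError, match="identical records"):
            loo_compare(clean_fit, other)

    def test_raw_importance_ratios_match_hand_computation(self):
        # 3 draws x 2 observations toy log-likelihood matrix
        ll = np.log(np.array([[0.5, 0.1], [0.25, 0.2], [0.125, 0.4]]))
        w = importance_ratios(ll)
        hand0 = np.array([1 / 0.5, 1 / 0.25, 1 / 0.125])
        hand0 /= hand0.sum()
        hand1 = np.array([1 / 0.1, 1 / 0.2, 1 / 0.4])
        hand1 /= hand1.sum()
        np.testing.assert_allclose(w[0], hand0, rtol=1e-12)
        np.testing.assert_allclose(w[1], hand1, rtol=1e-12)

    def test_hierarchical_beats_pooled_on_overdispersed_data(
            self, clean_foci_table, clean_fit):
        pooled = fit_foci_model(clean_foci_table,
                                SamplerSettings(steps=800, seed=21),
                                model="pooled")
        cmp = loo_compare(clean_fit, pooled)
        assert cmp.elpd_diff > 0
        assert cmp.preferred == "hierarchical"


class TestSimulationBasedCalibration:
    def test_sbc_ranks_uniform(self):
        """Rank statistics of true p_t among posterior draws are uniform
        when data are drawn from the model's own prior."""
        from scipy import stats
        from fluxfoci.foci_dynamics import sbc_ranks
        ranks = sbc_ranks(100, settings=SamplerSettings(steps=400, walkers=32),
                          seed=3)
        counts, _ = np.histogram(ranks.ravel(), bins=8, range=(-0.5, 63.5))
        assert stats.chisquare(counts).pvalue > 0.01


class TestBetaBinomialModel:
    def test_fits_and_recovers_rough_scale(self):
        cfg = FociSimConfig(p_curves={"a": (0.01, 0.03)}, times=(0.0, 0.5),
                            n_replicates=3, nuclei_per_replicate=25, seed=6)
        df = simulate_foci_dataset(cfg)
        post = fit_foci_model(df, SamplerSettings(steps=800, seed=7),
                              model="betabinom")
        med = np.median(post.p_t, axis=0)
        assert med[0] == pytest.approx(0.01, abs=0.01)
        assert med[1] == pytest.approx(0.03, abs=0.02)
        assert post.phi_t is not None
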