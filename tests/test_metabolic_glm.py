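"""Multilevel-GLM checks: HDI/P-minus primitives against closed forms,
deflection recovery on simulated studies, degenerate nesting, PPC."""

import numpy as np
import pandas as pd
import pytest

from fluxfoci import GLMSpec, fit_metabolic_glm, fit_time_course_glm, hdi, p_minus
from fluxfoci._mcmc import SamplerSettings
from fluxfoci.metabolic_glm import posterior_predictive_check


class TestHdi:
    def test_uniform_grid_window_ties_toward_lower_start(self):
        lo, hi = hdi(np.arange(1, 101, dtype=float), 0.5)
        assert (lo, hi) == (1.0, 50.0)

    def test_standard_normal_endpoints(self, rng):
        draws = rng.standard_normal(100_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_agrees_with_arviz_on_skewed_draws(self, rng):
        import arviz as az
        draws = rng.gamma(3.0, 2.0, size=50_000)
        lo, hi = hdi(draws, 0.9)
        ref = az.hdi(draws, hdi_prob=0.9)
        assert lo == pytest.approx(ref[0], abs=0.05)
        assert hi == pytest.approx(ref[1], abs=0.05)

    def test_point_mass_zero_width(self):
        lo, hi = hdi(np.full(200, 3.25), 0.95)
        assert lo == hi == 3.25

    def test_full_mass_spans_min_max(self, rng):
        draws = rng.standard_normal(500)
        assert hdi(draws, 1.0) == (draws.min(), draws.max())

    @pytest.mark.parametrize("mass", [0.0, -0.1, 1.5])
    def test_invalid_mass_rejected(self, mass):
        with pytest.raises(ValueError):
            hdi(np.arange(100.0), mass)


class TestPMinus:
    def test_all_negative_draws(self):
        assert p_minus(-np.arange(1.0, 11.0)) == 1.0

    def test_hand_counted_ten_draw_vector(self):
        draws = np.array([-3.0, -1.0, -0.5, -0.1, -0.01, 0.01, 0.2, 1.0, 2.0, 5.0])
        assert p_minus(draws) == 0.5
        assert p_minus(draws + 0.05) == 0.4

    def test_symmetric_draws_near_half(self, rng):
        assert p_minus(rng.standard_normal(20_000)) == pytest.approx(0.5, abs=0.02)

    def test_invariant_to_draw_order(self, rng):
        draws = rng.standard_normal(1000)
        assert p_minus(draws) == p_minus(np.sort(draws)[::-1])


def simulate_glm_data(deflections, wells=12, reps=2, resid_sd=0.1, seed=0,
                      grand_mean=3.0):
    rng = np.random.default_rng(seed)
    rows = []
    for cell, d in deflections.items():
        for r in range(1, reps + 1):
            rep_off = 0.03 * rng.standard_normal()
            for _ in range(wells):
                rows.append((cell, r, grand_mean + d + rep_off
                             + resid_sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["cell_line", "replicate", "value"])


class TestMetabolicGLM:
    def test_exchangeable_cell_lines_centered_at_zero(self, fast_sampler):
        df = simulate_glm_data({"a": 0.0, "b": 0.0}, seed=1)
        fit = fit_metabolic_glm(df, GLMSpec(sampler=fast_sampler))
        for eff in fit:
            assert abs(eff.median) < 0.1
            assert eff.p_minus == pytest.approx(0.5, abs=0.15)

    def test_signed_deflections_recovered(self, fast_sampler):
        df = simulate_glm_data({"neg": -0.5, "pos": 0.5}, seed=2)
        fit = fit_metabolic_glm(df, GLMSpec(sampler=fast_sampler))
        by = {e.level: e for e in fit}
        assert by["neg"].p_minus > 0.95
        assert by["pos"].p_minus < 0.05
        assert by["neg"].median == pytest.approx(-0.5, abs=0.15)

    def test_sum_to_zero_convention(self, fast_sampler):
        df = simulate_glm_data({"a": -0.3, "b": 0.1, "c": 0.2}, seed=3)
        fit = fit_metabolic_glm(df, GLMSpec(sampler=fast_sampler))
        total = sum(e.draws for e in fit)
        assert np.allclose(total, 0.0, atol=1e-12)

    def test_hdi50_nested_in_hdi95(self, fast_sampler):
        df = simulate_glm_data({"a": -0.2, "b": 0.2}, seed=4)
        for eff in fit_metabolic_glm(df, GLMSpec(sampler=fast_sampler)):
            assert eff.hdi95[0] <= eff.hdi50[0] <= eff.hdi50[1] <= eff.hdi95[1]
            assert np.isfinite(eff.rhat)

    def test_single_replicate_degrades_with_notice(self, fast_sampler, caplog):
        df = simulate_glm_data({"a": -0.4, "b": 0.4}, reps=1, seed=5)
        with caplog.at_level("WARNING"):
            fit = fit_metabolic_glm(df, GLMSpec(sampler=fast_sampler))
        assert "unidentified" in caplog.text
        assert {e.level for e in fit} == {"a", "b"}

    def test_nonfinite_values_rejected(self, fast_sampler):
        df = simulate_glm_data({"a": 0.0, "b": 0.0})
        df.loc[0, "value"] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_metabolic_glm(df, GLMSpec(sampler=fast_sampler))

    def test_determinism_under_seed(self):
        df = simulate_glm_data({"a": -0.2, "b": 0.2}, wells=4, seed=6)
        s = SamplerSettings(steps=300, seed=42)
        f1 = fit_metabolic_glm(df, GLMSpec(sampler=s))
        f2 = fit_metabolic_glm(df, GLMSpec(sampler=s))
        np.testing.assert_array_equal(f1.chains, f2.chains)


def simulate_time_course(deflections, times=(0.0, 1.0, 6.0), step=None,
                         seed=0, wells=8):
    rng = np.random.default_rng(seed)
    rows = []
    for cell, d in deflections.items():
        for r in (1, 2):
            for t in times:
                drop = step.get(t, 0.0) if step else 0.0
                for _ in range(wells):
                    rows.append((cell, r, t, 2.0 + d + drop
                                 + 0.1 * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["cell_line", "replicate", "time_h",
                                       "value"])


class TestTimeCourseGLM:
    def test_output_rows_are_cells_times_times(self, fast_sampler):
        df = simulate_time_course({"a": 0.0, "b": 0.0}, seed=1)
        fit = fit_time_course_glm(df, GLMSpec(sampler=fast_sampler))
        assert len(fit) == 2 * 3

    def test_identical_distributions_center_time_effects_at_zero(
            self, fast_sampler):
        df = simulate_time_course({"a": 0.0, "b": 0.0}, seed=2)
        fit = fit_time_course_glm(df, GLMSpec(sampler=fast_sampler))
        for eff in fit:
            assert abs(eff.median) < 0.12

    def test_step_drop_recovered_in_sign(self, fast_sampler):
        df = simulate_time_course({"a": 0.0, "b": 0.0},
                                  step={1.0: -0.6}, seed=3)
        fit = fit_time_course_glm(df, GLMSpec(sampler=fast_sampler))
        at_drop = [e for e in fit if e.level.endswith("@1.0h")]
        others = [e for e in fit if not e.level.endswith("@1.0h")]
        assert all(e.median < 0 and e.p_minus > 0.9 for e in at_drop)
        assert all(e.median > min(x.median for x in at_drop) for e in others)


class TestPPC:
    def test_self_generated_data_not_extreme(self, fast_sampler):
        df = simulate_glm_data({"a": -0.2, "b": 0.2}, seed=7)
        fit = fit_metabolic_glm(df, GLMSpec(sampler=fast_sampler))
        rep = posterior_predictive_check(fit, seed=1)
        assert set(rep.columns) >= {"statistic", "observed", "tail_prob"}
        assert len(rep) == 4  # mean, sd, two per-cell means
        ok = ((rep["tail_prob"] >= 0.05) & (rep["tail_prob"] <= 0.95)).sum()
        assert ok >= 3

    def test_mis_scaled_data_flagged_extreme(self, fast_sampler):
        df = simulate_glm_data({"a": -0.2, "b": 0.2}, seed=8)
        fit = fit_metabolic_glm(df, GLMSpec(sampler=fast_sampler))
        shifted = df.assign(value=df["value"] + 5.0)
        rep = posterior_predictive_check(fit, df=shifted, seed=1)
        mean_row = rep[rep["statistic"] == "mean"].iloc[0]
        # observed mean sits far above every replicated mean
        assert mean_row["tail_prob"] <= 0.01
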