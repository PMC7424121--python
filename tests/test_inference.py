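import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from morphcp import (
    ModelSpec,
    SimulationConfig,
    estimate_pse,
    filter_for_rt,
    fit_binomial_glmm,
    fit_linear_mixed,
    simulate,
    wald_type3,
)
from morphcp.inference import (
    SingularTermError,
    _aggregate_choices,
    _build_design,
    zero_sum_contrasts,
)
from oracles import quadrature_loglik


@pytest.fixture(scope="module")
def flat_sim():
    """Exp-1-sized simulation with no random variance and no lapse."""
    cfg = SimulationConfig(
        design="exp1", sd_participant=0.0, sd_continuum=0.0, lapse=0.0, seed=11
    )
    trials, _, _ = simulate(cfg)
    return trials


@pytest.fixture(scope="module")
def tiny_trials():
    """3 participants, 1 continuum, a handful of trials per cell."""
    cfg = SimulationConfig(
        design="exp1", n_participants=3, sd_participant=0.8, sd_continuum=0.0,
        lapse=0.0, seed=5,
    )
    trials, _, _ = simulate(cfg)
    sub = trials[trials["continuum_id"] == "uf1"]
    return sub.groupby(["participant_id", "morph_pct"]).head(3).reset_index(drop=True)


def test_zero_sum_contrast_columns_sum_to_zero():
    for k in (2, 3, 5):
        assert np.allclose(zero_sum_contrasts(k).sum(axis=0), 0.0)


class TestBinomialGlmm:
    def test_degenerate_variances_match_plain_logistic(self, flat_sim):
        fit = fit_binomial_glmm(flat_sim)
        assert all(s < 0.01 for s in fit.sigma.values())
        agg = _aggregate_choices(flat_sim)
        design = _build_design(agg, fit.spec, weights=agg["n"].to_numpy(float))
        glm = sm.GLM(
            np.column_stack([agg["k"], agg["n"] - agg["k"]]),
            design.X,
            family=sm.families.Binomial(),
        ).fit()
        assert np.abs(fit.beta - glm.params).max() < 1e-3
        # standard errors agree too once the random effects vanish
        assert np.abs(fit.se_beta() - glm.bse).max() < 1e-3

    def test_laplace_close_to_quadrature_on_tiny_instance(self, tiny_trials):
        spec = ModelSpec(response="choice", random=("participant_id",),
                         scaling="center50_div40")
        fit = fit_binomial_glmm(tiny_trials, spec)
        assert fit.converged
        exact = quadrature_loglik(
            tiny_trials, fit.beta, fit.sigma["participant_id"], spec
        )
        assert abs(fit.loglik - exact) < 0.1
        # the Laplace value should not exceed the exact likelihood materially
        assert fit.loglik <= exact + 0.01

    def test_recovers_generating_parameters_roughly(self, exp1_sim):
        trials, _, truth = exp1_sim
        fit = fit_binomial_glmm(trials)
        # logit slope per scaled unit: slope * (1 - lapse attenuates tails,
        # so only a loose sanity band)
        slope_per_unit = fit.beta[fit.term_slices["morph"]][0] / fit.scaling_scale
        assert 0.06 < slope_per_unit < 0.2
        assert 0.2 < fit.sigma["participant_id"] < 1.2
        assert fit.n_obs == 9720
        assert fit.n_groups == {"participant_id": 15, "continuum_id": 6}

    def test_deterministic_given_data(self, tiny_trials):
        spec = ModelSpec(response="choice", random=("participant_id",))
        a = fit_binomial_glmm(tiny_trials, spec)
        b = fit_binomial_glmm(tiny_trials, spec)
        assert np.array_equal(a.beta, b.beta)
        assert a.loglik == b.loglik

    def test_requires_two_participants(self, tiny_trials):
        one = tiny_trials[tiny_trials["participant_id"] == "P01"]
        with pytest.raises(ValueError, match="participants"):
            fit_binomial_glmm(one)


class TestLinearMixed:
    def test_degenerate_variances_match_ols(self, flat_sim):
        rt, _ = filter_for_rt(flat_sim)
        fit = fit_linear_mixed(rt)
        design = _build_design(rt, fit.spec)
        ols = sm.OLS(np.log(rt["rt_ms"].to_numpy()), design.X).fit()
        assert np.abs(fit.beta - ols.params).max() < 1e-4

    def test_single_participant_falls_back_to_fixed_effects(self, exp1_sim):
        trials, _, _ = exp1_sim
        one = trials[trials["participant_id"] == "P01"]
        rt, _ = filter_for_rt(one)
        fit = fit_linear_mixed(
            rt, ModelSpec(response="log_rt", random=("participant_id",))
        )
        assert fit.diagnostics["dropped_random"] == ["participant_id"]
        assert np.isnan(fit.sigma["participant_id"])
        assert fit.converged

    def test_translation_equivariance_of_log_rt(self, exp1_sim):
        """Multiplying all RTs by a constant shifts only the intercept."""
        trials, _, _ = exp1_sim
        rt, _ = filter_for_rt(trials)
        fit = fit_linear_mixed(rt)
        scaled = rt.copy()
        scaled["rt_ms"] = scaled["rt_ms"] * np.e  # +1 on the log scale
        fit2 = fit_linear_mixed(scaled)
        assert fit2.beta[0] - fit.beta[0] == pytest.approx(1.0, abs=1e-5)
        assert np.abs(fit2.beta[1:] - fit.beta[1:]).max() < 1e-5

    def test_recovers_condition_offset(self, exp1_sim):
        trials, _, truth = exp1_sim
        rt, _ = filter_for_rt(trials)
        fit = fit_linear_mixed(rt)
        j = fit.beta_names.index("cond[unfamiliar_familiar]")
        diff = 2.0 * fit.beta[j]  # effect coding: level difference = 2 beta
        true = truth["config"]["rt_condition_offsets"]["unfamiliar_familiar"]
        assert diff == pytest.approx(true, abs=3 * 2 * np.sqrt(fit.vcov_beta[j, j]))


class TestWaldType3:
    def test_one_df_term_equals_squared_z(self, exp1_sim):
        trials, _, _ = exp1_sim
        fit = fit_binomial_glmm(trials)
        wald = wald_type3(fit)
        for term in ("morph", "condition", "interaction"):
            s = fit.term_slices[term]
            z2 = (fit.beta[s][0] / fit.se_beta()[s][0]) ** 2
            assert wald.chi_square[term] == pytest.approx(z2, rel=1e-10)
            assert wald.df[term] == 1

    def test_zero_coefficients_give_zero_statistic(self, exp1_sim):
        trials, _, _ = exp1_sim
        fit = fit_binomial_glmm(trials)
        fit.beta[fit.term_slices["interaction"]] = 0.0
        wald = wald_type3(fit)
        assert wald.chi_square["interaction"] == 0.0
        assert wald.p_value["interaction"] == 1.0

    def test_singular_block_raises_naming_term(self, exp1_sim):
        trials, _, _ = exp1_sim
        fit = fit_binomial_glmm(trials)
        fit.vcov_beta[fit.term_slices["condition"], fit.term_slices["condition"]] = 0.0
        with pytest.raises(SingularTermError, match="condition"):
            wald_type3(fit)

    def test_relabeling_conditions_preserves_chi_square(self, exp2_sim):
        """Any zero-sum contrast basis gives identical Type-3 statistics, so
        permuting the condition level order must not change them."""
        trials, _, _ = exp2_sim
        levels = tuple(sorted(trials["condition"].unique()))
        fit1 = fit_binomial_glmm(trials, ModelSpec(condition_levels=levels))
        perm = tuple(np.roll(np.array(levels, dtype=object), 2))
        fit2 = fit_binomial_glmm(trials, ModelSpec(condition_levels=perm))
        w1, w2 = wald_type3(fit1), wald_type3(fit2)
        for term in ("morph", "condition", "interaction"):
            assert w1.chi_square[term] == pytest.approx(w2.chi_square[term], rel=1e-3)
        assert w1.df["condition"] == w1.df["interaction"] == 4


class TestPse:
    def test_zero_intercept_means_boundary_at_center(self, flat_sim):
        fit = fit_binomial_glmm(flat_sim)
        # force a clean closed form: intercept 0, no condition terms
        fit.beta[:] = 0.0
        fit.beta[fit.term_slices["morph"]] = 1.0
        est = estimate_pse(fit, "unfamiliar_familiar")
        # condition effects are zero, so the boundary sits at the scaling center
        assert est.pse == pytest.approx(fit.scaling_center)

    def test_closed_form_inversion(self, flat_sim):
        fit = fit_binomial_glmm(flat_sim)
        fit.beta[:] = 0.0
        # equivalent of intercept -1, slope 0.1 per morph unit around 50
        fit.beta[fit.term_slices["intercept"]] = -1.0
        fit.beta[fit.term_slices["morph"]] = 0.1 * fit.scaling_scale
        est = estimate_pse(fit, "unfamiliar_familiar")
        assert est.pse == pytest.approx(fit.scaling_center + 10.0)

    def test_zero_slope_is_an_error(self, flat_sim):
        fit = fit_binomial_glmm(flat_sim)
        fit.beta[fit.term_slices["morph"]] = 0.0
        fit.beta[fit.term_slices["interaction"]] = 0.0
        with pytest.raises(ZeroDivisionError, match="PSE"):
            estimate_pse(fit, "unfamiliar_familiar")

    def test_shift_estimate_points_toward_true_shift(self, exp1_sim):
        trials, _, truth = exp1_sim
        fit = fit_binomial_glmm(trials)
        est = estimate_pse(
            fit, "unfamiliar_familiar", reference="unfamiliar_unfamiliar"
        )
        true_shift = (
            truth["config"]["pse_by_condition"]["unfamiliar_familiar"]
            - truth["config"]["pse_by_condition"]["unfamiliar_unfamiliar"]
        )
        assert est.shift == pytest.approx(true_shift, abs=3 * est.shift_se)
        assert est.shift_se > 0

    def test_scaling_choice_does_not_move_the_pse(self, exp1_sim):
        trials, _, _ = exp1_sim
        fit_z = fit_binomial_glmm(trials, ModelSpec(scaling="zscore_over_trials"))
        fit_c = fit_binomial_glmm(trials, ModelSpec(scaling="center50_div40"))
        a = estimate_pse(fit_z, "unfamiliar_familiar")
        b = estimate_pse(fit_c, "unfamiliar_familiar")
        assert a.pse == pytest.approx(b.pse, abs=1e-3)
        assert a.se == pytest.approx(b.se, rel=1e-3)
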