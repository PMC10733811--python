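"""Shifted-lognormal model: priors, fitting, marginal means, contrasts."""

import numpy as np
import pandas as pd
import pytest

from conflictlab.behavior import BehaviorParams, filter_trials, simulate_behavior
from conflictlab.rtmodel import (
    CELLS,
    EMMTable,
    HalfNormalPrior,
    MCMCConfig,
    ModelSpec,
    NormalPrior,
    PointPrior,
    PosteriorFit,
    PriorSpec,
    SpecificationError,
    adaptive_control_contrasts,
    fit_shifted_lognormal,
    marginal_means,
    posterior_predictive_quantiles,
    prior_predictive,
    transfer_priors,
)
from tests.conftest import balanced_table


def make_fake_fit(draw_values: dict, converged=True) -> PosteriorFit:
    """PosteriorFit stub with hand-set draws of shape (1, n)."""
    draws = {k: np.atleast_2d(np.asarray(v, float)) for k, v in draw_values.items()}
    coef_names = [k for k in draws if k.startswith(("mu0", "beta"))]
    return PosteriorFit(
        draws=draws,
        coef_names=coef_names,
        groups=["HC"],
        spec=ModelSpec(),
        config=MCMCConfig(chains=1, warmup=0, draws=len(next(iter(draws.values()))[0])),
        rhat={k: 1.0 for k in draws},
        converged=converged,
        model=None,
    )


class TestPriorPredictive:
    def test_default_priors_yield_plausible_rts(self):
        design = balanced_table(10, n_participants=4)
        out = prior_predictive(ModelSpec(), design, n_draws=2000, seed=0)
        assert out["plausible"]
        assert 150 <= out["q2.5"] and out["q97.5"] <= 5000

    def test_point_mass_priors_give_shifted_lognormal_median(self):
        design = balanced_table(25, n_participants=2)
        priors = PriorSpec(
            intercept=NormalPrior(6.0, 0.0),
            effect=NormalPrior(0.0, 0.0),
            sigma=PointPrior(0.3),
            tau_participant=PointPrior(0.0),
            tau_item=PointPrior(0.0),
            shift=PointPrior(200.0),
        )
        out = prior_predictive(
            ModelSpec(priors=priors), design, n_draws=400, seed=1
        )
        # median of delta + exp(Normal(mu, sigma)) is delta + e^mu
        assert out["median"] == pytest.approx(200 + np.exp(6), rel=0.02)

    def test_degenerate_sigma_prior_rejected(self):
        with pytest.raises(SpecificationError):
            PriorSpec(sigma=HalfNormalPrior(0.0))
        priors = PriorSpec(sigma=PointPrior(0.0))
        with pytest.raises(SpecificationError):
            prior_predictive(
                ModelSpec(priors=priors), balanced_table(2), n_draws=5, seed=0
            )


class TestFit:
    @pytest.fixture(scope="class")
    def fitted(self):
        table = balanced_table(40, n_participants=8)
        true = BehaviorParams(
            shift_ms=200, intercept=6.0, beta_congruency=0.10,
            sigma=0.3, tau_participant=0.1, tau_item=0.05,
        )
        sim = simulate_behavior(table, true, seed=42)
        sim, _ = filter_trials(sim)
        fit = fit_shifted_lognormal(
            sim, ModelSpec(),
            MCMCConfig(chains=2, warmup=300, draws=500, seed=0),
            min_trials_per_cell=30,
        )
        return fit

    def test_recovers_congruency_effect(self, fitted):
        bc = fitted.flat("beta_congruency[HC]")
        lo, hi = np.percentile(bc, [2.5, 97.5])
        assert lo <= 0.10 <= hi

    def test_rhat_recorded_for_every_parameter(self, fitted):
        for name in fitted.draws:
            assert name in fitted.rhat

    def test_draw_counts_match_config(self, fitted):
        assert fitted.draws["sigma"].shape == (2, 500)

    def test_shift_below_group_minimum(self, fitted):
        delta = fitted.flat("delta[HC]")
        assert np.all(delta > 0)
        assert np.all(delta < fitted.model.rt.min())

    def test_posterior_predictive_brackets_observed(self, fitted):
        sim_q = posterior_predictive_quantiles(fitted, n_rep=100, seed=0)
        observed = fitted.model.rt
        for q, draws in sim_q.items():
            obs = np.quantile(observed, q)
            lo, hi = np.percentile(draws, [1, 99])
            assert lo <= obs <= hi

    def test_sparse_participant_excluded(self):
        table = balanced_table(45, n_participants=4)
        extra = balanced_table(30, n_participants=1).assign(
            participant_id="sparse"
        )
        sim = simulate_behavior(
            pd.concat([table, extra], ignore_index=True), BehaviorParams(), seed=0
        )
        fit = fit_shifted_lognormal(
            sim, ModelSpec(), MCMCConfig(chains=2, warmup=50, draws=50, seed=0),
            min_trials_per_cell=40,
        )
        assert fit.excluded_participants == ["sparse"]
        assert "sparse" not in fit.model.participants


class TestMarginalMeans:
    def test_single_draw_hand_computed(self):
        fit = make_fake_fit(
            {
                "mu0[HC]": [6.0],
                "beta_congruency[HC]": [0.1],
                "sigma": [0.0],
                "delta[HC]": [200.0],
            }
        )
        emm = marginal_means(fit)
        assert emm.draws[("HC", "incongruent", "MC")][0] == pytest.approx(
            200 + np.exp(6.05), abs=0.01
        )  # 624.1 ms
        assert emm.draws[("HC", "congruent", "MC")][0] == pytest.approx(
            200 + np.exp(5.95), abs=0.01
        )  # 583.7 ms

    def test_null_betas_give_identical_cells(self):
        fit = make_fake_fit(
            {"mu0[HC]": [6.1, 6.2], "sigma": [0.2, 0.3], "delta[HC]": [150, 180]}
        )
        emm = marginal_means(fit)
        ref = emm.draws[("HC",) + CELLS[0]]
        for cell in CELLS[1:]:
            assert np.allclose(emm.draws[("HC",) + cell], ref)

    def test_emm_monotone_in_mu0(self):
        fit = make_fake_fit(
            {"mu0[HC]": [5.9, 6.0, 6.1], "sigma": [0.3] * 3, "delta[HC]": [200] * 3}
        )
        emm = marginal_means(fit)
        vals = emm.draws[("HC", "congruent", "MC")]
        assert vals[0] < vals[1] < vals[2]

    def test_median_mode_drops_variance_term(self):
        fit = make_fake_fit(
            {"mu0[HC]": [6.0], "sigma": [0.4], "delta[HC]": [100.0]}
        )
        mean_emm = marginal_means(fit, mode="mean")
        med_emm = marginal_means(fit, mode="median")
        cell = ("HC", "congruent", "MC")
        assert med_emm.draws[cell][0] == pytest.approx(100 + np.exp(6.0))
        assert mean_emm.draws[cell][0] > med_emm.draws[cell][0]


class TestContrasts:
    def emm_from_cells(self, cong_mc, incg_mc, cong_mi, incg_mi):
        return EMMTable(
            draws={
                ("HC", "congruent", "MC"): np.array([cong_mc]),
                ("HC", "incongruent", "MC"): np.array([incg_mc]),
                ("HC", "congruent", "MI"): np.array([cong_mi]),
                ("HC", "incongruent", "MI"): np.array([incg_mi]),
            },
            groups=["HC"],
            mode="mean",
        )

    def test_arithmetic_identity(self):
        table = adaptive_control_contrasts(self.emm_from_cells(600, 680, 640, 660))
        d = table.draws
        assert d[("HC", "conflict_MC")][0] == 80
        assert d[("HC", "conflict_MI")][0] == 20
        assert d[("HC", "interaction")][0] == -60
        assert d[("HC", "incongruent_improvement")][0] == -20

    def test_identical_conditions_zero_interaction(self):
        table = adaptive_control_contrasts(self.emm_from_cells(600, 650, 600, 650))
        assert table.draws[("HC", "interaction")][0] == 0.0

    def test_missing_cell_rejected(self):
        emm = self.emm_from_cells(600, 680, 640, 660)
        del emm.draws[("HC", "congruent", "MI")]
        with pytest.raises(KeyError):
            adaptive_control_contrasts(emm)

    def test_between_group_difference(self):
        emm = self.emm_from_cells(600, 680, 640, 660)
        emm.draws.update(
            {
                ("PD", "congruent", "MC"): np.array([700.0]),
                ("PD", "incongruent", "MC"): np.array([760.0]),
                ("PD", "congruent", "MI"): np.array([720.0]),
                ("PD", "incongruent", "MI"): np.array([755.0]),
            }
        )
        emm.groups = ["HC", "PD"]
        table = adaptive_control_contrasts(emm, pairing=("HC", "PD"))
        # HC improvement -20, PD improvement -5
        assert table.draws[("between", "improvement_difference")][0] == -15


class TestTransferPriors:
    def test_widen_factor_definition(self, rng):
        draws = rng.normal(0.10, 0.02, 4000)
        fit = make_fake_fit({"beta_congruency[HC]": draws})
        priors = transfer_priors(fit, widen=2.0)
        prior = priors.effect_prior("beta_congruency[HC]")
        assert prior.loc == pytest.approx(0.10, abs=0.005)
        assert prior.scale == pytest.approx(0.04, abs=0.005)

    def test_widen_one_keeps_posterior_sd(self, rng):
        draws = rng.normal(0.0, 0.05, 4000)
        fit = make_fake_fit({"beta_interaction[HC]": draws})
        priors = transfer_priors(fit, widen=1.0)
        assert priors.effect_prior("beta_interaction[HC]").scale == pytest.approx(
            0.05, abs=0.005
        )

    def test_nonconverged_fit_refused(self):
        fit = make_fake_fit({"beta_congruency[HC]": [0.1, 0.2]}, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            transfer_priors(fit)

    def test_transferred_priors_shrink_toward_inducer_estimate(self):
        """Paired fits on one null data set: informative priors centred on
        a nonzero inducer interaction pull the posterior toward it."""
        table = balanced_table(40, n_participants=6)
        sim = simulate_behavior(
            table, BehaviorParams(tau_participant=0.05, tau_item=0.02), seed=7
        )
        sim, _ = filter_trials(sim)
        mcmc = MCMCConfig(chains=2, warmup=200, draws=300, seed=1)
        default_fit = fit_shifted_lognormal(
            sim, ModelSpec(), mcmc, min_trials_per_cell=30
        )
        inducer_value = -0.15
        priors = PriorSpec(
            effect_overrides={
                "beta_interaction[HC]": NormalPrior(inducer_value, 0.02)
            }
        )
        informed_fit = fit_shifted_lognormal(
            sim, ModelSpec(priors=priors), mcmc, min_trials_per_cell=30
        )
        b_def = default_fit.flat("beta_interaction[HC]").mean()
        b_inf = informed_fit.flat("beta_interaction[HC]").mean()
        assert abs(b_inf - inducer_value) < abs(b_def - inducer_value)
        assert b_inf < b_def


class TestModelSpecValidation:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(SpecificationError):
            ModelSpec(include=frozenset({"interaction"}))

    def test_unknown_factor_rejected(self):
        with pytest.raises(SpecificationError):
            ModelSpec(include=frozenset({"congruency", "speed"}))
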