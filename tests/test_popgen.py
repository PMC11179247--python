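"""Generative-model unit and property tests.

The mediator law implied by the three exposure logits has an independent
closed form via the law of total probability; the tests below hold the
implementation to it, and to exact enumeration for the true effects.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import crossmed as cm
from crossmed import popgen
from crossmed.popgen import (
    ConfigurationError,
    GenerativeValidityError,
    linear_predictors,
    prob_A,
    prob_A_given_M,
    prob_M_given_A,
)


def oracle_prob_M(a, b, d, a_level):
    """Independent total-probability solution for P(M=1 | A=a_level)."""
    p = (expit(a) - expit(b)) / (expit(b + d) - expit(b))
    if a_level == 1:
        return expit(b + d) * p / expit(a)
    return (1 - expit(b + d)) * p / (1 - expit(a))


class TestLinearPredictors:
    def test_zero_coefficients_give_intercepts(self, scenario1):
        spec = cm.ScenarioSpec(1, (0.0,) * 7, (0.0,) * 7, 0.0, scenario1.y_model)
        C = pd.DataFrame([[1, 0, 1, 0, 1, 0]], columns=list(popgen.COVARIATES))
        a, b, d = linear_predictors(C, spec)
        assert a[0] == pytest.approx(0.68)
        assert b[0] == pytest.approx(0.80)
        assert d[0] == pytest.approx(-1.52)

    @pytest.mark.parametrize("x2,expected", [(1, -2.02), (0, -1.52)])
    def test_delta_interaction_enters_through_x2(self, x2, expected):
        spec = cm.ScenarioSpec.default(5)  # delta = -0.5
        C = pd.DataFrame([[0, 0, 0, 0, x2, 0]], columns=list(popgen.COVARIATES))
        _, _, d = linear_predictors(C, spec)
        assert d[0] == pytest.approx(expected)


class TestExposureAndMediatorProbabilities:
    def test_logistic_at_zero(self):
        assert prob_A(0.0) == pytest.approx(0.5)

    def test_conditional_exposure_levels(self):
        assert prob_A_given_M(0.8, -1.52, 1) == pytest.approx(1 / (1 + np.exp(0.72)))
        assert prob_A_given_M(0.8, -1.52, 0) == pytest.approx(expit(0.8))
        # d = 0 removes the mediator dependence
        assert prob_A_given_M(0.3, 0.0, 1) == prob_A_given_M(0.3, 0.0, 0)

    def test_mediator_law_matches_independent_oracle_values(self):
        # frozen from the total-probability oracle at (0.5, 0.8, -1.52)
        assert prob_M_given_A(0.5, 0.8, -1.52, 1) == pytest.approx(0.097939, abs=1e-6)
        assert prob_M_given_A(0.5, 0.8, -1.52, 0) == pytest.approx(0.331736, abs=1e-6)

    def test_equal_logits_give_degenerate_mediator(self):
        assert prob_M_given_A(0.8, 0.8, -1.52, 1) == pytest.approx(0.0)

    @given(
        frac=st.floats(0.05, 0.95),
        b=st.floats(-1.0, 2.0),
        d=st.floats(-2.5, -0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_mediator_law_equals_oracle_on_feasible_grid(self, frac, b, d):
        a = b + frac * d  # b + d < a < b by construction
        for lvl in (0, 1):
            assert prob_M_given_A(a, b, d, lvl) == pytest.approx(
                oracle_prob_M(a, b, d, lvl), abs=1e-12
            )

    @given(
        frac=st.floats(0.05, 0.95),
        b=st.floats(-1.0, 2.0),
        d=st.floats(-2.5, -0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_marginal_coherence(self, frac, b, d):
        """Sum_m P(A=1|M=m) P(M=m) reconstructs the marginal P(A=1)."""
        a = b + frac * d
        pM1 = (
            prob_M_given_A(a, b, d, 1) * prob_A(a)
            + prob_M_given_A(a, b, d, 0) * (1 - prob_A(a))
        )
        recon = prob_A_given_M(b, d, 1) * pM1 + prob_A_given_M(b, d, 0) * (1 - pM1)
        assert recon == pytest.approx(prob_A(a), abs=1e-12)

    def test_infeasible_combination_is_rejected(self):
        # a > b makes P(M=1|A=1) negative
        with pytest.raises(GenerativeValidityError):
            prob_M_given_A(1.5, 0.8, -1.52, 1)

    def test_d_zero_with_unequal_logits_is_rejected(self):
        with pytest.raises(GenerativeValidityError):
            prob_M_given_A(0.5, 0.8, 0.0, 1)


class TestSpecsAndCovariates:
    def test_default_scenarios_all_feasible(self):
        for sid in range(1, 9):
            cm.ScenarioSpec.default(sid)  # feasibility enumerated at construction

    def test_scenario_interaction_table_enforced(self, scenario1):
        y = dict(scenario1.y_model)
        y["A:M"] = 0.3
        with pytest.raises(ConfigurationError):
            cm.ScenarioSpec(1, popgen.DEFAULT_ALPHA, popgen.DEFAULT_BETA, 0.0, y)
        with pytest.raises(ConfigurationError):  # scenario 5 demands delta != 0
            cm.ScenarioSpec(5, popgen.DEFAULT_ALPHA, popgen.DEFAULT_BETA, 0.0,
                            scenario1.y_model)

    def test_degenerate_covariate_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            cm.StratumSpec(1, (0.3, -0.4, -0.2, 0.25, 0.2, np.inf))

    def test_stratum_sizes_and_covariate_means(self, strata):
        n = 30_000
        cov = popgen.generate_covariates(3 * n, strata, rng_seed=11)
        counts = cov["stratum"].value_counts()
        assert set(counts.index) == {1, 2, 3} and (counts == n).all()
        # stratum-1 U1 rate matches the link-transformed latent value 0.3
        p = expit(0.3)
        got = cov.loc[cov.stratum == 1, "U1"].mean()
        assert abs(got - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_generation_is_deterministic_under_seed(self, scenario1):
        a = cm.generate_population(999, spec=scenario1, rng_seed=5)
        b = cm.generate_population(999, spec=scenario1, rng_seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_uneven_n_spreads_remainder(self, strata):
        cov = popgen.generate_covariates(100, strata, rng_seed=0)
        assert sorted(cov["stratum"].value_counts()) == [33, 33, 34]


class TestPopulationConsistency:
    def test_observed_equal_potential_at_observed_exposure(self, small_population):
        pop = small_population
        on_a1 = pop.A == 1
        assert (pop.loc[on_a1, "M"] == pop.loc[on_a1, "M1"]).all()
        assert (pop.loc[~on_a1, "M"] == pop.loc[~on_a1, "M0"]).all()
        assert (pop.loc[on_a1, "Y"] == pop.loc[on_a1, "Y11"]).all()
        assert (pop.loc[~on_a1, "Y"] == pop.loc[~on_a1, "Y00"]).all()

    def test_population_roundtrips_through_csv(self, small_population, tmp_path):
        path = tmp_path / "pop.csv"
        popgen.write_population_csv(small_population.head(50), path)
        back = popgen.read_population_csv(path)
        pd.testing.assert_frame_equal(
            back, small_population.head(50)[back.columns], check_dtype=False
        )


class TestTrueEffects:
    def test_decompositions_hold_exactly(self, small_population, strata, scenario8):
        for truth in (cm.true_effects_mc(small_population),
                      cm.true_effects_exact(strata, scenario8)):
            assert truth.te == truth.nde0 + truth.nie1
            assert truth.te == truth.nde1 + truth.nie0

    def test_mc_requires_potential_outcomes(self, small_population):
        with pytest.raises(ValueError):
            cm.true_effects_mc(small_population[["A", "M", "Y"]])

    def test_null_outcome_model_gives_half_everywhere(self, strata):
        spec = cm.ScenarioSpec(1, popgen.DEFAULT_ALPHA, popgen.DEFAULT_BETA, 0.0, {})
        truth = cm.true_effects_exact(strata, spec)
        for po in (truth.po11, truth.po00, truth.po10, truth.po01):
            assert po == pytest.approx(0.5)
        assert truth.te == pytest.approx(0.0)

    def test_outcome_without_mediator_terms_has_zero_indirect_effect(self, strata):
        y = {"intercept": -0.5, "A": 0.7, "U1": 0.3, "X2": -0.4}
        spec = cm.ScenarioSpec(1, popgen.DEFAULT_ALPHA, popgen.DEFAULT_BETA, 0.0, y)
        truth = cm.true_effects_exact(strata, spec)
        assert truth.nie1 == pytest.approx(0.0, abs=1e-15)
        assert truth.nie0 == pytest.approx(0.0, abs=1e-15)
        assert truth.te != 0.0

    def test_monte_carlo_converges_to_exact(self, strata, scenario1):
        n = 200_000
        pop = cm.generate_population(n, strata, scenario1, rng_seed=123)
        mc = cm.true_effects_mc(pop)
        exact = cm.true_effects_exact(strata, scenario1)
        for name in ("po11", "po00", "po10", "po01"):
            p = getattr(exact, name)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(getattr(mc, name) - p) < 4 * se
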