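"""Regression engine, trend models, selection and weight derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import analysis_frame_for, noise_free_config
from saltscore import CohortConfig
from saltscore.errors import DegenerateDataError, DomainError, SingularDesignError
from saltscore.modeling import (RegressionResult, derive_weights, fit_ols,
                                per_item_trend, select_variables, stepwise_select)
from saltscore.synthetic import FOOD_GROUPS, generate_cohort


def normal_equations_oracle(y, X):
    """Independent brute-force solve of (X'X) b = X'y with textbook SEs."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


class TestFitOLS:
    def test_exact_fit_no_noise(self):
        x = np.arange(10.0)
        y = 1.0 + 2.0 * x
        fit = fit_ols(y, np.column_stack([np.ones(10), x]))
        assert np.allclose(fit.params, [1.0, 2.0])
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 51))
            p = int(rng.integers(2, 9))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            fit = fit_ols(y, X)
            beta, se = normal_equations_oracle(y, X)
            assert np.allclose(fit.params, beta, rtol=1e-8)
            assert np.allclose(fit.se, se, rtol=1e-8)

    def test_permutation_invariance(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.normal(size=30)
        fit = fit_ols(y, X)
        perm = rng.permutation(30)
        fit_p = fit_ols(y[perm], X[perm])
        assert np.allclose(fit.params, fit_p.params)
        assert np.allclose(fit.pvalues, fit_p.pvalues)

    def test_singular_design_names_columns(self, rng):
        x = rng.normal(size=25)
        X = np.column_stack([np.ones(25), x, 2 * x])
        with pytest.raises(SingularDesignError) as err:
            fit_ols(rng.normal(size=25), X, names=["intercept", "a", "a_doubled"])
        assert "a_doubled" in err.value.columns

    def test_underdetermined(self, rng):
        with pytest.raises(DomainError):
            fit_ols(rng.normal(size=3), rng.normal(size=(3, 4)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_property_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(10, 40)), int(rng.integers(2, 6))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.normal(size=n)
        beta, _ = normal_equations_oracle(y, X)
        assert np.allclose(fit_ols(y, X).params, beta, rtol=1e-7)


class TestPerItemTrend:
    def test_slope_recovery_within_two_se(self):
        """Marginal trend of an item with a strong direct effect: the true
        slope lies within 2 SEs in at least 90 of 100 replicates."""
        hits = 0
        for r in range(100):
            cfg = CohortConfig(n_participants=500, lambda_x=2.0, behavior_corr=0.0,
                               ffq_item_noise=0.0,
                               true_weights_na={"taste_preference": 210.0},
                               intercept_na=3500.0, seed=300 + r)
            frame = analysis_frame_for(generate_cohort(cfg))
            res = per_item_trend(frame, "taste_preference", "sodium_mg")
            hits += abs(res.slope - 210.0) <= 2 * res.se
        assert hits >= 90

    def test_constant_item_raises(self, default_analysis_frame):
        frame = default_analysis_frame.copy()
        frame["taste_preference"] = 3
        with pytest.raises(SingularDesignError):
            per_item_trend(frame, "taste_preference", "sodium_mg")

    def test_constant_outcome_degenerate(self, default_analysis_frame):
        frame = default_analysis_frame.copy()
        frame["na_mg_per_day"] = 4000.0
        with pytest.warns(UserWarning, match="degenerate"):
            res = per_item_trend(frame, "taste_preference", "sodium_mg")
        assert res.slope == 0.0


def _rr(item, p):
    return RegressionResult(item, 1.0, 1.0, p, [], 100)


class TestSelectVariables:
    def test_significant_in_both_selected(self):
        r1 = [_rr("a", 0.01), _rr("b", 0.20)]
        r2 = [_rr("a", 0.04), _rr("b", 0.01)]
        assert select_variables(r1, r2) == ["a"]

    def test_single_instrument_significance_dropped(self):
        r1 = [_rr("wasabi", 0.30)]
        r2 = [_rr("wasabi", 0.0001)]
        assert select_variables(r1, r2) == []

    def test_order_preserved(self):
        r1 = [_rr("c", 0.01), _rr("a", 0.01), _rr("b", 0.5)]
        r2 = [_rr("a", 0.01), _rr("b", 0.01), _rr("c", 0.01)]
        assert select_variables(r1, r2) == ["c", "a"]

    def test_mismatched_items_error(self):
        with pytest.raises(DomainError):
            select_variables([_rr("a", 0.1)], [_rr("b", 0.1)])

    def test_monotone_in_alpha(self, rng):
        items = [f"i{k}" for k in range(10)]
        r1 = [_rr(i, rng.uniform()) for i in items]
        r2 = [_rr(i, rng.uniform()) for i in items]
        sel_small = set(select_variables(r1, r2, alpha=0.05))
        sel_big = set(select_variables(r1, r2, alpha=0.5))
        assert sel_small <= sel_big


class TestStepwise:
    def test_single_strong_group(self, rng):
        n = 300
        X = pd.DataFrame({f"g{k}": rng.integers(1, 5, n).astype(float)
                          for k in range(5)})
        y = 2.0 + 0.5 * X["g2"].to_numpy() + rng.normal(0, 0.5, n)
        res = stepwise_select(X, y)
        assert "g2" in res.selected

    def test_three_true_groups_recovered(self):
        hits = 0
        for r in range(10):
            cfg = CohortConfig(n_participants=500, seed=600 + r)
            frame = analysis_frame_for(generate_cohort(cfg))
            res = stepwise_select(frame[[f"{g}_q" for g in FOOD_GROUPS]],
                                  frame["nak_mol"].to_numpy())
            truth = {"vegetables_q", "fruits_q", "milk_products_q"}
            hits += truth <= set(res.selected)
        assert hits >= 8

    def test_null_returns_empty_or_few(self, rng):
        X = pd.DataFrame({f"g{k}": rng.normal(size=200) for k in range(17)})
        y = rng.normal(size=200)
        res = stepwise_select(X, y, entry=1e-6, stay=1e-6)
        assert res.selected == []


class TestDeriveWeights:
    def test_noise_free_exact_recovery(self):
        cfg = noise_free_config()
        frame = analysis_frame_for(generate_cohort(cfg))
        eq = derive_weights(frame, list(cfg.true_weights_na), "sodium_mg")
        assert eq.intercept == pytest.approx(cfg.intercept_na, rel=1e-6)
        for item, w in cfg.true_weights_na.items():
            assert eq.coefficients[item] == pytest.approx(w, rel=1e-6)

    def test_noise_free_exact_recovery_nak(self):
        cfg = noise_free_config()
        frame = analysis_frame_for(generate_cohort(cfg))
        eq = derive_weights(frame, list(cfg.true_weights_nak), "nak_mol")
        assert eq.intercept == pytest.approx(cfg.intercept_nak, rel=1e-6)
        for item, w in cfg.true_weights_nak.items():
            assert eq.coefficients[item] == pytest.approx(w, rel=1e-6)

    def test_characteristics_toggle_adds_four(self, default_analysis_frame):
        items = ["taste_preference", "soy_sauce"]
        eq0 = derive_weights(default_analysis_frame, items, "sodium_mg",
                             include_characteristics=False)
        eq1 = derive_weights(default_analysis_frame, items, "sodium_mg",
                             include_characteristics=True)
        assert len(eq1.coefficients) - len(eq0.coefficients) == 4
        assert {"sex", "age", "bmi", "htn_med"} <= set(eq1.coefficients)

    def test_empty_selection_rejected(self, default_analysis_frame):
        with pytest.raises(DegenerateDataError):
            derive_weights(default_analysis_frame, [], "sodium_mg")
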