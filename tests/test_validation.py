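"""Split, scoring, deattenuation, variance components and agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import analysis_frame_for
from saltscore import CohortConfig
from saltscore.errors import (DegenerateDataError, DomainError, PredictionError)
from saltscore.modeling import PredictionEquation
from saltscore.synthetic import generate_cohort
from saltscore.urine import daily_values
from saltscore.validation import (balanced_split, bland_altman, compare_approaches,
                                  deattenuate, estimate_lambda, predict,
                                  predict_frame, spearman_cc)


def _strata_frame(rng, n=244):
    return pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(n)],
        "sex": rng.choice([1, 2], n),
        "top_na_quartile": rng.choice([0, 1], n, p=[0.75, 0.25]),
        "taste_preference": rng.integers(1, 5, n),
    })


class TestBalancedSplit:
    def test_within_stratum_balance(self, rng):
        frame = _strata_frame(rng)
        split = balanced_split(frame, seed=0)
        sizes = split.groupby(["sex", "top_na_quartile", "taste_preference"])[
            "group"].value_counts().unstack(fill_value=0)
        diff = (sizes.get("development", 0) - sizes.get("validation", 0)).abs()
        assert (diff <= 1).all()

    def test_two_member_stratum_split(self):
        frame = pd.DataFrame({"participant_id": ["a", "b"], "sex": [1, 1],
                              "top_na_quartile": [0, 0], "taste_preference": [2, 2]})
        split = balanced_split(frame, seed=5)
        assert set(split["group"]) == {"development", "validation"}

    def test_seed_determinism(self, rng):
        frame = _strata_frame(rng)
        a = balanced_split(frame, seed=3)
        b = balanced_split(frame, seed=3)
        pd.testing.assert_frame_equal(a, b)
        c = balanced_split(frame, seed=4)
        assert not a["group"].equals(c["group"])

    def test_empty_cohort_error(self):
        with pytest.raises(DomainError):
            balanced_split(pd.DataFrame(columns=["participant_id", "sex",
                                                 "top_na_quartile",
                                                 "taste_preference"]), seed=0)


SODIUM_BEHAVIOR_WEIGHTS = PredictionEquation(
    "sodium_mg", 2523.0,
    {"taste_preference": 47.0, "soy_sauce": 187.0, "noodle_soup": 199.0,
     "pickled_vegetables": 101.0, "miso_soup_bowls": 161.0}, False)

NAK_BEHAVIOR_WEIGHTS = PredictionEquation(
    "nak_mol", 2.89,
    {"taste_preference": 0.18, "soy_sauce": 0.32, "vegetables_q": -0.18,
     "fruits_q": -0.18, "milk_products_q": -0.13}, False)

SODIUM_CHARACTERISTIC_WEIGHTS = PredictionEquation(
    "sodium_mg", 865.0,
    {"taste_preference": 145.0, "soy_sauce": 87.0, "noodle_soup": 104.0,
     "pickled_vegetables": 163.0, "miso_soup_bowls": 170.0,
     "sex": -529.0, "age": 3.0, "bmi": 102.0, "htn_med": 30.0}, True)


class TestPredict:
    def test_behavior_only_sodium_hand_sum(self):
        record = {v: 1 for v in SODIUM_BEHAVIOR_WEIGHTS.coefficients}
        assert predict(SODIUM_BEHAVIOR_WEIGHTS, record) == pytest.approx(3218.0)

    def test_behavior_only_nak_hand_sum(self):
        record = {v: 1 for v in NAK_BEHAVIOR_WEIGHTS.coefficients}
        assert predict(NAK_BEHAVIOR_WEIGHTS, record) == pytest.approx(2.90)

    def test_with_characteristics_hand_sum(self):
        record = {"taste_preference": 1, "soy_sauce": 1, "noodle_soup": 1,
                  "pickled_vegetables": 1, "miso_soup_bowls": 1,
                  "sex": 1, "age": 50.0, "bmi": 23.0, "htn_med": 0}
        assert predict(SODIUM_CHARACTERISTIC_WEIGHTS, record) == pytest.approx(3501.0)

    def test_missing_variable_named(self):
        with pytest.raises(PredictionError) as err:
            predict(SODIUM_BEHAVIOR_WEIGHTS, {"taste_preference": 1})
        assert err.value.variable == "soy_sauce"

    def test_frame_matches_scalar(self, rng):
        frame = pd.DataFrame({v: rng.integers(1, 5, 10)
                              for v in SODIUM_BEHAVIOR_WEIGHTS.coefficients})
        vec = predict_frame(SODIUM_BEHAVIOR_WEIGHTS, frame)
        for i in range(10):
            assert vec[i] == pytest.approx(
                predict(SODIUM_BEHAVIOR_WEIGHTS, frame.iloc[i]))


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert spearman_cc(x, x**3) == pytest.approx(1.0)
        assert spearman_cc(x, -x) == pytest.approx(-1.0)

    def test_ties_match_midrank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 7.0, 6.0])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_cc(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(DegenerateDataError):
            spearman_cc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLambdaEstimate:
    def _days(self, values_by_person):
        rows = [{"participant_id": pid, "na_mg": v}
                for pid, vals in values_by_person.items() for v in vals]
        return pd.DataFrame(rows)

    def test_identical_days_per_person(self):
        days = self._days({"a": [100.0] * 4, "b": [200.0] * 4, "c": [300.0] * 4})
        est = estimate_lambda(days, "na_mg")
        assert est.lambda_x == pytest.approx(0.0)
        assert est.n_collections == pytest.approx(4.0)

    def test_shared_mean_clamps_between_component(self):
        # both persons share the mean 2.0; between-person component <= 0
        with pytest.warns(UserWarning, match="between-person"):
            est = estimate_lambda(self._days({"a": [1.0, 3.0], "b": [3.0, 1.0]}),
                                  "na_mg")
        assert est.clamped and est.lambda_x > 0

    def test_single_day_persons_rejected(self):
        with pytest.raises(DomainError):
            estimate_lambda(self._days({"a": [1.0], "b": [2.0]}), "na_mg")


class TestDeattenuate:
    def test_zero_lambda_identity(self):
        assert deattenuate(0.37, 0.0, 4) == pytest.approx(0.37)

    def test_printed_example(self):
        assert deattenuate(0.40, 1.0, 4) == pytest.approx(0.4472, abs=5e-5)

    def test_large_n_limit(self):
        assert deattenuate(0.40, 1.0, 1e9) == pytest.approx(0.40, abs=1e-6)

    def test_out_of_range_flagged(self):
        with pytest.warns(UserWarning, match="outside"):
            v = deattenuate(0.9, 3.0, 2)
        assert v == pytest.approx(0.9 * np.sqrt(2.5))

    def test_order_preserving(self, rng):
        ccs = np.sort(rng.uniform(-1, 1, 20))
        adj = [deattenuate(c, 1.7, 4.3) for c in ccs]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_invalid_n(self):
        with pytest.raises(DomainError):
            deattenuate(0.4, 1.0, 0.5)


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mean_diff == 0.0 and ba.loa_lower == 0.0 and ba.loa_upper == 0.0

    def test_constant_offset(self):
        ba = bland_altman([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert ba.mean_diff == pytest.approx(1.0)
        assert ba.sd_diff == pytest.approx(0.0)

    def test_linear_shrinkage_negative_slope(self, rng):
        meas = rng.normal(4200, 700, 200)
        est = meas.mean() + 0.5 * (meas - meas.mean())
        ba = bland_altman(est, meas)
        # closed form: d = -0.5 (meas - mean), m = mean + 0.75 (meas - mean)
        assert ba.prop_bias_slope == pytest.approx(-0.5 / 0.75, rel=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            bland_altman([1.0, 2.0], [1.0])


@pytest.fixture(scope="module")
def setting():
    cfg = CohortConfig(seed=17)
    cohort = generate_cohort(cfg)
    frame = analysis_frame_for(cohort)
    days = daily_values(cohort.urine_days)
    equations = {
        "sodium": {"behavior_only": SODIUM_BEHAVIOR_WEIGHTS},
        "nak": {"behavior_only": NAK_BEHAVIOR_WEIGHTS},
    }
    return frame, days[days.missed_voids == 0], equations


class TestCompareApproaches:

    def test_report_structure(self, setting):
        frame, days, equations = setting
        rows = compare_approaches(frame, days, equations)
        assert {(r["outcome"], r["stratum"]) for r in rows} == {
            (o, s) for o in ("sodium", "nak") for s in ("all", "male", "female")}
        for r in rows:
            assert -1 <= r["crude_cc"] <= 1
            assert r["ba_loa"][0] <= r["ba_loa"][1]
            assert r["lambda_x"] >= 0

    def test_adjusted_exceeds_crude_for_positive_cc(self, setting):
        frame, days, equations = setting
        for r in compare_approaches(frame, days, equations):
            if r["crude_cc"] >= 0:
                assert r["adjusted_cc"] >= r["crude_cc"]

    def test_perfect_comparator_beats_equation(self, setting):
        """With an error-free food-composition estimator, its crude CC for
        sodium must exceed the noisy questionnaire equation's."""
        cfg = CohortConfig(seed=23, fci_error_sd=0.0, ffq_item_noise=0.35)
        cohort = generate_cohort(cfg)
        frame = analysis_frame_for(cohort)
        days = daily_values(cohort.urine_days)
        equations = {"sodium": {"behavior_only": SODIUM_BEHAVIOR_WEIGHTS},
                     "nak": {"behavior_only": NAK_BEHAVIOR_WEIGHTS}}
        rows = compare_approaches(frame, days[days.missed_voids == 0], equations,
                                  energy_method="none")
        row = next(r for r in rows if r["outcome"] == "sodium"
                   and r["stratum"] == "all")
        assert row["comparator_crude_cc"] > row["crude_cc"]

    def test_permuted_measured_null_band(self, setting, rng):
        frame, days, equations = setting
        shuffled = frame.copy()
        perm = rng.permutation(len(frame))
        for col in ("na_mg_per_day", "nak_mol"):
            shuffled[col] = frame[col].to_numpy()[perm]
        rows = compare_approaches(shuffled, days, equations)
        for r in rows:
            if r["stratum"] == "all":
                assert abs(r["crude_cc"]) < 3.0 / np.sqrt(r["n"])
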