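"""Age-adjusted group comparison, significance tiers, KIDSCREEN scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from craniometrics.errors import CollinearDesignError, ValidationError
from craniometrics.stats_outcomes import (
    BAND_LABELS,
    DEFAULT_ITEM_MAP,
    group_compare,
    kidscreen_scores,
    load_norms,
    percentile_band,
    significance_tier,
)
from oracles import band_oracle, kidscreen_oracle, pooled_t_test, welch_t_test


def _cohort(rng, n=40, effect=0.0, age_slope=0.0, sigma=1.0):
    age = rng.uniform(3, 16, n * 2)
    group = np.repeat(["control", "case"], n)
    value = 10 + age_slope * age + effect * (group == "case") + rng.normal(0, sigma, n * 2)
    return pd.DataFrame(
        {"subject": [f"s{i}" for i in range(n * 2)], "group": group,
         "age_months": age, "value": value}
    )


class TestGroupCompare:
    def test_identical_groups_have_zero_difference_p_one(self, rng):
        vals = rng.normal(10, 2, 20)
        ages = rng.uniform(3, 16, 20)
        cohort = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(40)],
                "group": np.repeat(["a", "b"], 20),
                "age_months": np.concatenate([ages, ages]),
                "value": np.concatenate([vals, vals]),
            }
        )
        res = group_compare(cohort, "value", "a", "b")
        assert res.difference == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_age_adjusted_model_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        for _ in range(10):
            cohort = _cohort(rng, n=25, effect=2.0, age_slope=0.3)
            res = group_compare(cohort, "value", "control", "case")
            X = sm.add_constant(
                np.column_stack(
                    [(cohort["group"] == "case").astype(float), cohort["age_months"]]
                )
            )
            fit = sm.OLS(cohort["value"], X).fit()
            assert res.difference == pytest.approx(fit.params.iloc[1], rel=1e-9)
            assert res.p_value == pytest.approx(fit.pvalues.iloc[1], rel=1e-9)

    def test_unadjusted_test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            cohort = _cohort(rng, n=rng.integers(5, 30), effect=rng.normal(0, 2))
            x = cohort.loc[cohort["group"] == "case", "value"].to_numpy()
            y = cohort.loc[cohort["group"] == "control", "value"].to_numpy()
            res = group_compare(cohort, "value", "control", "case", adjust_age=False)
            _, p = pooled_t_test(x, y)
            assert res.p_value == pytest.approx(p, rel=1e-12)
            res_w = group_compare(cohort, "value", "control", "case",
                                  adjust_age=False, welch=True)
            _, p_w = welch_t_test(x, y)
            assert res_w.p_value == pytest.approx(p_w, rel=1e-12)

    def test_zero_age_slope_reduces_to_unadjusted_difference(self, rng):
        cohort = _cohort(rng, n=200, effect=5.0, age_slope=0.0, sigma=0.5)
        adj = group_compare(cohort, "value", "control", "case")
        raw = group_compare(cohort, "value", "control", "case", adjust_age=False)
        assert adj.difference == pytest.approx(raw.difference, abs=0.2)

    def test_parameter_recovery_with_age_confound(self, rng):
        """value = 0.3*age + 5*group + N(0,1): the ANCOVA recovers the
        injected effect (full 100-replicate coverage runs in acceptance)."""
        cohort = _cohort(rng, n=50, effect=5.0, age_slope=0.3)
        res = group_compare(cohort, "value", "control", "case")
        assert res.difference == pytest.approx(5.0, abs=0.7)
        assert res.p_value < 0.001

    def test_constant_age_is_collinear(self, rng):
        cohort = _cohort(rng, n=10)
        cohort["age_months"] = 7.0
        with pytest.raises(CollinearDesignError, match="collinear design"):
            group_compare(cohort, "value", "control", "case")

    def test_too_few_subjects_rejected(self, rng):
        cohort = _cohort(rng, n=2)
        with pytest.raises(ValidationError):
            group_compare(cohort, "value", "control", "case")


class TestSignificanceTier:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.005, "highly significant"),
            (0.03, "significant"),
            (0.07, "mildly significant"),
            (0.5, "not significant"),
            (0.01, "significant"),        # boundaries fall to the weaker tier
            (0.05, "mildly significant"),
            (0.1, "not significant"),
            (0.0, "highly significant"),
            (1.0, "not significant"),
        ],
    )
    def test_tier_mapping(self, p, label):
        assert significance_tier(p) == label

    def test_monotone_step_function(self):
        order = ["highly significant", "significant", "mildly significant", "not significant"]
        grid = np.linspace(0, 1, 2001)
        ranks = [order.index(significance_tier(p)) for p in grid]
        assert ranks == sorted(ranks)

    @pytest.mark.parametrize("bad", [-0.1, 1.5, float("nan")])
    def test_invalid_probability_rejected(self, bad):
        with pytest.raises(ValidationError):
            significance_tier(bad)

    @settings(deadline=None, derandomize=True)
    @given(
        p=st.floats(min_value=0, max_value=1),
        q=st.floats(min_value=0, max_value=1),
    )
    def test_tier_rank_never_decreases_with_p(self, p, q):
        order = ["highly significant", "significant", "mildly significant", "not significant"]
        lo, hi = sorted((p, q))
        assert order.index(significance_tier(lo)) <= order.index(significance_tier(hi))


def _responses(rng, n_subjects=10):
    data = rng.integers(1, 6, size=(n_subjects, 52)).astype(float)
    return pd.DataFrame(data, columns=[f"q{i}" for i in range(1, 53)],
                        index=[f"s{i}" for i in range(n_subjects)])


class TestKidscreenScores:
    def test_endpoint_and_midpoint_values(self, rng):
        resp = _responses(rng, 3)
        resp.iloc[0] = 1.0
        resp.iloc[1] = 5.0
        resp.iloc[2] = 3.0
        scores = kidscreen_scores(resp)
        assert (scores.iloc[0] == 0.0).all()
        assert (scores.iloc[1] == 100.0).all()
        assert (scores.iloc[2] == 50.0).all()
        assert scores.shape[1] == 10

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(100):
            resp = _responses(rng, 1)
            scores = kidscreen_scores(resp)
            expected = kidscreen_oracle(resp.iloc[0].to_dict(), DEFAULT_ITEM_MAP)
            for cat, val in expected.items():
                assert scores.iloc[0][cat] == pytest.approx(val, abs=1e-12)

    def test_permutation_invariance_within_category(self, rng):
        resp = _responses(rng, 1)
        items = [i for i, c in DEFAULT_ITEM_MAP.items() if c == "moods_emotions"]
        shuffled = resp.copy()
        shuffled[items] = resp[items].iloc[:, ::-1].to_numpy()
        assert kidscreen_scores(resp).equals(kidscreen_scores(shuffled))

    def test_missing_items_yield_nan_not_imputation(self, rng):
        resp = _responses(rng, 1)
        resp.loc[resp.index[0], "q1"] = np.nan
        scores = kidscreen_scores(resp)
        assert np.isnan(scores.iloc[0]["physical_wellbeing"])
        assert not scores.iloc[0].drop("physical_wellbeing").isna().any()

    def test_one_based_variant_spans_1_to_100(self, rng):
        resp = _responses(rng, 2)
        resp.iloc[0] = 1.0
        resp.iloc[1] = 5.0
        scores = kidscreen_scores(resp, one_based=True)
        assert (scores.iloc[0] == 1.0).all()
        assert (scores.iloc[1] == 100.0).all()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        item_idx=st.integers(min_value=1, max_value=52),
        r1=st.integers(min_value=1, max_value=5),
        r2=st.integers(min_value=1, max_value=5),
    )
    def test_score_is_affine_in_each_response(self, item_idx, r1, r2):
        """Changing one item by k response steps moves its category score by
        exactly k * 25 / n_items points."""
        base = pd.DataFrame([np.full(52, 3.0)], columns=[f"q{i}" for i in range(1, 53)])
        item = f"q{item_idx}"
        cat = DEFAULT_ITEM_MAP[item]
        n_items = sum(1 for c in DEFAULT_ITEM_MAP.values() if c == cat)
        a, b = base.copy(), base.copy()
        a[item], b[item] = float(r1), float(r2)
        sa = kidscreen_scores(a).iloc[0][cat]
        sb = kidscreen_scores(b).iloc[0][cat]
        assert sb - sa == pytest.approx((r2 - r1) * 25.0 / n_items, abs=1e-12)

    def test_out_of_range_responses_rejected(self, rng):
        resp = _responses(rng, 1)
        resp.iloc[0, 0] = 6.0
        with pytest.raises(ValidationError):
            kidscreen_scores(resp)


class TestPercentileBand:
    def test_boundary_scores_fall_in_upper_band(self):
        norms = load_norms()
        cuts = norms.loc["autonomy", ["p10", "p25", "p50", "p75", "p90"]]
        assert percentile_band(cuts["p50"], norms, "autonomy") == "P50-P75"
        assert percentile_band(cuts["p10"] - 1, norms, "autonomy") == "<P10"
        assert percentile_band(cuts["p90"], norms, "autonomy") == ">P90"

    def test_matches_brute_force_interval_search(self, rng):
        norms = load_norms()
        for _ in range(200):
            cat = rng.choice(norms.index)
            score = rng.uniform(0, 100)
            cuts = norms.loc[cat, ["p10", "p25", "p50", "p75", "p90"]].tolist()
            assert percentile_band(score, norms, cat) == band_oracle(score, cuts, BAND_LABELS)

    def test_missing_category_rejected(self):
        with pytest.raises(ValidationError):
            percentile_band(50.0, load_norms(), "nonexistent")
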