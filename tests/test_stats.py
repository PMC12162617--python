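"""Mann-Whitney, subject aggregates, permutation importance, regressions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from settledown import RFParams, mann_whitney, permutation_importance, posthoc_regression
from settledown.features import FEATURE_NAMES
from settledown.stats import group_tests, regression_table, subject_aggregates
from settledown.types import ChildRecord, SettlingPeriod

from oracles import mann_whitney_pairs, ols_normal_equations
from test_classify import toy_table


class TestMannWhitney:
    def test_identical_samples(self):
        u, z, _ = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n1*n2/2
        assert z == pytest.approx(0.0)

    @pytest.mark.parametrize("x,y,expect", [((1, 2), (3, 4), 0.0), ((1, 3), (2, 4), 1.0)])
    def test_pair_counting_examples(self, x, y, expect):
        u, _, _ = mann_whitney(x, y)
        assert u == expect

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n1, n2 = int(rng.integers(1, 12)), int(rng.integers(1, 12))
            x = rng.integers(0, 8, n1).astype(float)
            y = rng.integers(0, 8, n2).astype(float)
            if len(set(x) | set(y)) < 2:
                continue
            u, _, _ = mann_whitney(x, y)
            assert u == mann_whitney_pairs(x, y)

    def test_u_plus_u_prime_is_n1n2(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=9), rng.normal(size=7)
        u1, _, _ = mann_whitney(x, y)
        u2, _, _ = mann_whitney(y, x)
        assert u1 + u2 == pytest.approx(63.0)

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 20, 15).astype(float)
        y = rng.integers(5, 25, 12).astype(float)
        u, _, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mann_whitney([5, 5], [5, 5, 5])


def _period(child, day, minutes, group="SS", fill=0.0):
    start = pd.Timestamp(f"2021-10-{day:02d} 21:00")
    return SettlingPeriod(child, start.date(), group, start,
                          start + pd.Timedelta(minutes=minutes),
                          np.full(minutes, fill))


class TestSubjectAggregates:
    def test_two_night_duration_stats(self):
        periods = [_period("a", 1, 40), _period("a", 2, 60)]
        table = pd.DataFrame(
            {
                "child_id": ["a", "a"],
                "night_date": [p.night_date for p in periods],
                "group": "SS",
                "window_start": [p.start for p in periods],
                **{f: [1.0, 2.0] for f in FEATURE_NAMES},
            }
        )
        (row,) = subject_aggregates(table, periods).to_dict("records")
        assert row["mean_settling_min"] == 50.0
        assert row["sd_settling_min"] == pytest.approx(np.sqrt(200), abs=1e-9)

    def test_hand_computed_three_night_fixture(self):
        periods = [_period("a", d, 20) for d in (1, 2, 3)]
        # hand-listed windows: night 1 has two windows, nights 2-3 one each
        table = pd.DataFrame(
            {
                "child_id": "a",
                "night_date": [periods[0].night_date, periods[0].night_date,
                               periods[1].night_date, periods[2].night_date],
                "group": "SS",
                "window_start": range(4),
                "mean_mag": [100.0, 200.0, 300.0, 400.0],
                "max_mag": [500.0, 900.0, 700.0, 800.0],
                "kurtosis": 0.0,
                "skewness": 0.0,
                "entropy_bits": [3.0, 1.0, 2.0, 2.5],
                "sd": 1.0,
                "iqr": 1.0,
            }
        )
        (row,) = subject_aggregates(table, periods).to_dict("records")
        assert row["mean_magnitude"] == 250.0                      # mean of 4 windows
        assert row["mean_max_magnitude"] == (900 + 700 + 800) / 3  # per-night maxima
        assert row["median_entropy"] == 2.25
        assert row["mean_settling_min"] == 20.0

    def test_child_without_windows_excluded(self):
        periods = [_period("a", 1, 30), _period("b", 1, 30)]
        table = pd.DataFrame(
            {
                "child_id": ["a"], "night_date": [periods[0].night_date],
                "group": ["SS"], "window_start": [0],
                **{f: [1.0] for f in FEATURE_NAMES},
            }
        )
        agg = subject_aggregates(table, periods)
        assert agg["child_id"].tolist() == ["a"]

    def test_records_supply_age_and_sex(self):
        periods = [_period("a", 1, 30)]
        table = pd.DataFrame(
            {
                "child_id": ["a"], "night_date": [periods[0].night_date],
                "group": ["SS"], "window_start": [0],
                **{f: [1.0] for f in FEATURE_NAMES},
            }
        )
        agg = subject_aggregates(table, periods, [ChildRecord("a", "SS", 8.5, "F")])
        assert agg.loc[0, "age_years"] == 8.5 and agg.loc[0, "sex"] == "F"


class TestPermutationImportance:
    def test_constant_column_near_zero_drop(self):
        table = toy_table(80, sep=2.0, seed=1)
        table["kurtosis"] = 1.0
        imp = permutation_importance(table, RFParams(n_trees=25, seed=0), n_repeats=3, seed=0)
        row = imp[imp.feature_name == "kurtosis"].iloc[0]
        assert abs(row.mean_auc_decrease) < 0.05

    def test_label_driving_feature_ranks_first(self):
        rng = np.random.default_rng(7)
        table = toy_table(150, sep=0.0, seed=2)  # all features pure noise...
        table["max_mag"] = rng.normal(size=len(table))
        table["group"] = np.where(table["max_mag"] > 0, "SS", "NSS")  # ...except max_mag
        imp = permutation_importance(table, RFParams(n_trees=40, seed=0), n_repeats=3, seed=0)
        assert imp.iloc[0].feature_name == "max_mag"
        second = imp.iloc[1].mean_auc_decrease
        assert imp.iloc[0].mean_auc_decrease > second + 0.1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            permutation_importance(toy_table(0), RFParams())


def _aggregate_frame(n=16, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "child_id": [f"c{i}" for i in range(n)],
            "group": ["SS", "NSS"] * (n // 2),
            "age_years": rng.uniform(6, 10, n).round(1),
            "sex": rng.choice(["M", "F"], n),
            "mean_settling_min": rng.uniform(15, 90, n).round(1),
            "sd_settling_min": rng.uniform(5, 30, n).round(1),
            "mean_magnitude": rng.uniform(1500, 3000, n).round(1),
            "mean_max_magnitude": rng.uniform(6000, 14000, n).round(1),
            "median_entropy": rng.uniform(2.2, 3.46, n).round(2),
        }
    )
    return df


class TestRegression:
    def test_matches_normal_equations_oracle(self):
        df = _aggregate_frame(12, seed=5)
        res = posthoc_regression(df, "mean_max_magnitude")
        X = np.column_stack(
            [
                (df["group"] == "SS").astype(float),
                df["mean_max_magnitude"],
                df["age_years"],
                (df["sex"] == "M").astype(float),
            ]
        )
        beta, r2, f = ols_normal_equations(X, df["mean_settling_min"])
        assert res.constant == pytest.approx(beta[0], rel=1e-9)
        for b, name in zip(beta[1:], ("group", "mean_max_magnitude", "age_years", "sex")):
            assert res.unstandardized_betas[name] == pytest.approx(b, rel=1e-9)
        assert res.r_squared == pytest.approx(r2, rel=1e-9)
        assert res.f_stat == pytest.approx(f, rel=1e-9)

    def test_exact_linear_outcome_standardized_beta_one(self):
        df = _aggregate_frame(20, seed=6)
        df["mean_settling_min"] = 2.0 * df["median_entropy"]
        res = posthoc_regression(df, "median_entropy")
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.standardized_betas["median_entropy"] == pytest.approx(1.0, abs=1e-9)

    def test_uninformative_predictor_beta_near_zero(self):
        df = _aggregate_frame(200, seed=7)
        res0 = posthoc_regression(df, None)
        res1 = posthoc_regression(df, "median_entropy")  # independent noise
        assert abs(res1.standardized_betas["median_entropy"]) < 0.15
        assert res1.r_squared == pytest.approx(res0.r_squared, abs=0.03)

    def test_nested_model_r2_monotone(self):
        df = _aggregate_frame(24, seed=8)
        base = posthoc_regression(df, None).r_squared
        for pred in ("mean_magnitude", "mean_max_magnitude", "sd_settling_min", "median_entropy"):
            assert posthoc_regression(df, pred).r_squared >= base - 1e-12

    def test_singular_design_rejected(self):
        df = _aggregate_frame(12, seed=9)
        df["sex"] = "F"
        with pytest.raises(ValueError, match="singular|zero variance"):
            posthoc_regression(df, None)

    def test_regression_table_shape(self):
        df = _aggregate_frame(16, seed=10)
        tab = regression_table(df)
        assert tab.shape[1] == 5
        assert "model_3_mean_max_magnitude" in tab.columns
        assert {"r_squared", "f_stat", "n_obs"} <= set(tab.index)


def test_group_tests_table(calibrated_table, calibrated_periods):
    included, _, _, dataset = calibrated_periods
    agg = subject_aggregates(calibrated_table, included, list(dataset.children.values()))
    out = group_tests(agg)
    assert len(out) == 5
    # calibrated cohort: SS more active and slower to settle
    direction = out.set_index("variable")
    assert direction.loc["mean_settling_min", "ss_mean"] > direction.loc["mean_settling_min", "nss_mean"]
    assert direction.loc["mean_max_magnitude", "ss_mean"] > direction.loc["mean_max_magnitude", "nss_mean"]
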