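import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rrtuplift import (
    BenefitLogistic,
    build_nomogram,
    compare_groups,
    fit_benefit_logistic,
    power_two_proportions,
    two_proportion_test,
)


def two_group_frame(rng, n_per=138, shift=0.0):
    n = 2 * n_per
    df = pd.DataFrame(
        {
            "lactate": rng.lognormal(1.0, 0.6, n),
            "wbc": rng.normal(15, 6, n),
            "flag": rng.integers(0, 2, n),
        }
    )
    labels = pd.Series(["high"] * n_per + ["low"] * n_per)
    df.loc[: n_per - 1, "wbc"] += shift
    return df, labels


class TestCompareGroups:
    def test_identical_groups_show_no_difference(self):
        rng = np.random.default_rng(0)
        half = pd.DataFrame({"lactate": rng.lognormal(1, 0.5, 60), "flag": rng.integers(0, 2, 60)})
        df = pd.concat([half, half], ignore_index=True)
        labels = pd.Series(["high"] * 60 + ["low"] * 60)
        out = compare_groups(df, labels, ["lactate", "flag"]).set_index("variable")
        assert out.loc["lactate", "p"] > 0.9
        assert out.loc["flag", "p"] == pytest.approx(1.0)

    def test_two_sd_shift_is_detected(self):
        # power oracle: +2 SD mean shift at n=138/138 is essentially always
        # significant at 0.001 for any of the candidate tests
        rng = np.random.default_rng(1)
        df, labels = two_group_frame(rng, shift=12.0)  # 2 x sd(wbc)
        out = compare_groups(df, labels, ["wbc"]).set_index("variable")
        assert out.loc["wbc", "p"] < 0.001

    def test_binary_matches_hand_computed_chi_square(self):
        df = pd.DataFrame({"flag": [1] * 30 + [0] * 70 + [1] * 50 + [0] * 50})
        labels = pd.Series(["high"] * 100 + ["low"] * 100)
        out = compare_groups(df, labels, ["flag"]).iloc[0]
        chi2, p, _, _ = stats.chi2_contingency([[30, 70], [50, 50]], correction=True)
        assert out["test"] == "chi-square"
        assert out["statistic"] == pytest.approx(chi2)
        assert out["p"] == pytest.approx(p)

    def test_selection_rule_tracks_distribution_shape(self):
        rng = np.random.default_rng(2)
        n = 300
        df = pd.DataFrame({"gauss": rng.normal(0, 1, n), "skewed": rng.lognormal(0, 1.2, n)})
        labels = pd.Series(rng.permutation(["high", "low"] * (n // 2)))
        out = compare_groups(df, labels, ["gauss", "skewed"]).set_index("variable")
        assert out.loc["gauss", "test"] == "t"
        assert out.loc["skewed", "test"] == "mann-whitney"

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"k": [5.0] * 20})
        labels = pd.Series(["high"] * 10 + ["low"] * 10)
        out = compare_groups(df, labels, ["k"]).iloc[0]
        assert out["test"] == "constant" and np.isnan(out["p"])

    def test_null_pvalues_uniform(self):
        # KS check on 500 null replications of the continuous comparison
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(500):
            df = pd.DataFrame({"v": rng.normal(0, 1, 100)})
            labels = pd.Series(["high"] * 50 + ["low"] * 50)
            ps.append(compare_groups(df, labels, ["v"])["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bh_correction_is_opt_in(self):
        rng = np.random.default_rng(4)
        df, labels = two_group_frame(rng)
        out = compare_groups(df, labels, ["lactate", "wbc"])
        assert "p_bh" not in out.columns
        out_bh = compare_groups(df, labels, ["lactate", "wbc"], bh_correction=True)
        assert "p_bh" in out_bh.columns


class TestBenefitLogistic:
    def test_null_labels_show_no_association(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(0, 1, (10_000, 6)), columns=list("abcdef"))
        tab = fit_benefit_logistic(df, rng.integers(0, 2, 10_000), list("abcdef"))
        # joint null check sized for 6 simultaneous comparisons
        assert (tab["p"] > 0.001).all()
        assert tab["OR"].between(0.8, 1.25).all()

    def test_recovers_known_coefficient(self):
        rng = np.random.default_rng(7)
        n, beta = 50_000, 0.5
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-beta * x))).astype(int)
        df = pd.DataFrame({"x": x})
        res = BenefitLogistic(df, y, ["x"]).fit()
        se = (np.log(res.or_table()["CI_high"][0]) - np.log(res.or_table()["CI_low"][0])) / 3.92
        assert abs(np.log(res.or_table()["OR"][0]) - beta) < 3 * se

    def test_fewer_rows_than_parameters_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 6)), columns=list("abcdef"))
        with pytest.raises(ValueError, match="fewer rows"):
            BenefitLogistic(df, [0, 1, 0, 1, 0], list("abcdef"))

    def test_separation_raises(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        with pytest.raises(ValueError):
            BenefitLogistic(df, y, ["x"]).fit()

    def test_or_table_and_summary_shape(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        y = (rng.random(500) < 1 / (1 + np.exp(-df["a"]))).astype(int)
        res = BenefitLogistic(df, y, ["a", "b"]).fit()
        tab = res.or_table()
        assert list(tab.columns) == ["variable", "OR", "CI_low", "CI_high", "p"]
        assert (tab["CI_low"] <= tab["OR"]).all() and (tab["OR"] <= tab["CI_high"]).all()
        assert "OR" in res.summary()


class TestNomogram:
    def _fitted(self, seed=0, n=800):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "urine_output": rng.lognormal(7.3, 0.7, n),
                "lactate": rng.lognormal(1.0, 0.7, n),
                "resp_rate": rng.normal(20, 4, n),
            }
        )
        eta = -0.001 * df["urine_output"] + 0.3 * df["lactate"] + 0.1 * (df["resp_rate"] - 20)
        y = (rng.random(n) < 1 / (1 + np.exp(-(eta - eta.mean())))).astype(int)
        return df, BenefitLogistic(df, y, list(df.columns)).fit()

    def test_round_trip_probability(self):
        df, res = self._fitted()
        nom = build_nomogram(res)
        rng = np.random.default_rng(42)
        profiles = df.sample(1000, random_state=1, replace=True)
        delta = np.abs(nom.predict_proba(profiles) - res.predict_proba(profiles))
        assert delta.max() < 0.01

    def test_points_nonnegative_and_max_100(self):
        df, res = self._fitted()
        nom = build_nomogram(res)
        maxima = []
        for v in nom.variables:
            ax = nom.axis_table(v, n=51)
            assert (ax["points"] >= -1e-9).all()
            maxima.append(ax["points"].max())
        assert max(maxima) == pytest.approx(100.0)

    def test_single_variable_points_linear(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"lactate": rng.lognormal(1, 0.6, 500)})
        y = (rng.random(500) < 1 / (1 + np.exp(-0.5 * (df["lactate"] - 3)))).astype(int)
        res = BenefitLogistic(df, y, ["lactate"]).fit()
        nom = build_nomogram(res, {"lactate": (0.0, 10.0)})
        ax = nom.axis_table("lactate", n=11)
        diffs = np.diff(ax["points"])
        assert np.allclose(diffs, diffs[0])
        assert ax["points"].iloc[-1] == pytest.approx(100.0)

    def test_negative_coefficient_peaks_at_low_end(self):
        df, res = self._fitted()
        assert res.params["urine_output"] < 0  # benefit falls with diuresis
        nom = build_nomogram(res)
        ax = nom.axis_table("urine_output")
        assert ax["points"].iloc[0] == ax["points"].max()
        assert ax["points"].iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_probability_increases_in_total_points(self):
        _, res = self._fitted()
        nom = build_nomogram(res)
        tab = nom.total_points_table(n=30)
        assert np.all(np.diff(tab["probability"]) > 0)

    def test_json_export(self):
        import json

        _, res = self._fitted()
        nom = build_nomogram(res)
        d = json.loads(nom.to_json())
        assert set(d["axes"]) == set(nom.variables)
        assert "total_points_to_probability" in d

    def test_all_zero_coefficients_rejected(self):
        from rrtuplift.profiling import Nomogram  # noqa: F401  (type import)

        _, res = self._fitted()
        res.params[:] = 0.0
        with pytest.raises(ValueError, match="zero"):
            build_nomogram(res, {v: (0.0, 1.0) for v in res.model.variables})


class TestTwoProportionTest:
    def test_equal_rates_not_significant(self):
        stat, p = two_proportion_test(50, 100, 50, 100)
        assert p == pytest.approx(1.0)

    def test_matched_cohort_mortality_contrast(self):
        # 28-day deaths 148/458 vs 180/458 (32.3% vs 39.3%)
        _, p = two_proportion_test(148, 458, 180, 458)
        assert round(p, 3) == 0.033

    def test_symmetric_in_group_order(self):
        s1, p1 = two_proportion_test(148, 458, 180, 458)
        s2, p2 = two_proportion_test(180, 458, 148, 458)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_agrees_with_exact_test_on_small_counts(self):
        for e1, n1, e2, n2 in [(3, 20, 9, 20), (5, 30, 12, 30), (2, 15, 8, 15)]:
            _, p = two_proportion_test(e1, n1, e2, n2)
            fisher = stats.fisher_exact([[e1, n1 - e1], [e2, n2 - e2]])[1]
            assert abs(p - fisher) < 0.05  # Yates approximates the exact test

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            two_proportion_test(0, 10, 0, 10)

    def test_events_bounded_by_n(self):
        with pytest.raises(ValueError):
            two_proportion_test(11, 10, 5, 10)


class TestPower:
    def test_size_equals_level_under_null(self):
        assert power_two_proportions(0.3, 0.3, 500) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_sample_size(self):
        powers = [power_two_proportions(0.393, 0.323, n) for n in [50, 100, 200, 400, 800]]
        assert powers == sorted(powers)

    def test_matches_monte_carlo_rejection_rate(self):
        # oracle: 100,000 simulated trials analysed with the pooled z-test
        p1, p2, n = 0.393, 0.323, 458
        rng = np.random.default_rng(5)
        x1 = rng.binomial(n, p1, 100_000)
        x2 = rng.binomial(n, p2, 100_000)
        pool = (x1 + x2) / (2 * n)
        z = (x1 / n - x2 / n) / np.sqrt(2 * pool * (1 - pool) / n)
        mc = float(np.mean(np.abs(z) > stats.norm.ppf(0.975)))
        assert abs(power_two_proportions(p1, p2, n) - mc) < 0.01

    def test_ttest_variant_close_to_normal(self):
        a = power_two_proportions(0.393, 0.323, 458, method="normal")
        b = power_two_proportions(0.393, 0.323, 458, method="ttest")
        assert abs(a - b) < 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_two_proportions(0.0, 0.3, 100)
        with pytest.raises(ValueError):
            power_two_proportions(0.3, 0.4, 1)
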