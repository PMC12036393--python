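import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mirv import (
    build_design_matrix,
    dichotomize,
    fit_cox,
    km_logrank,
    subgroup_analysis,
)
from mirv.survival_stats import CoxFitError

from conftest import cox_partial_loglik


def _design(times, events, x):
    return pd.DataFrame({"os_time_years": times, "os_event": events, "x": x})


class TestFitCox:
    def test_symmetric_groups_give_zero_coefficient(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        x = [0, 0, 0, 1, 1, 1]
        res = fit_cox(_design(times, events, x))
        assert res.summary.loc[0, "coef"] == pytest.approx(0.0, abs=1e-6)
        assert res.n_events == 6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_partial_likelihood_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        times = rng.permutation(np.arange(1, n + 1)).astype(float)  # distinct, no ties
        x = rng.integers(0, 2, n).astype(float)
        events = np.ones(n, int)
        events[rng.integers(0, n)] = 0
        if x.std() == 0 or events.sum() == 0:
            pytest.skip("degenerate draw")
        res = fit_cox(_design(times, events, x))
        oracle = minimize_scalar(
            lambda b: -cox_partial_loglik(b, times, events, x),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-8},
        ).x
        assert res.summary.loc[0, "coef"] == pytest.approx(oracle, abs=1e-4)

    def test_simulated_hr_two_is_covered_by_ci(self):
        rng = np.random.default_rng(123)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.5 * np.exp(np.log(2) * x)))
        c = rng.exponential(4.0, n)
        res = fit_cox(
            _design(np.minimum(t, c), (t <= c).astype(int), x)
        )
        assert res.summary.loc[0, "ci_lower"] < 2.0 < res.summary.loc[0, "ci_upper"]
        assert res.summary.loc[0, "coef"] == pytest.approx(np.log(2), abs=0.3)
        assert res.summary.loc[0, "hr"] == pytest.approx(
            np.exp(res.summary.loc[0, "coef"])
        )

    def test_zero_events_rejected(self):
        with pytest.raises(CoxFitError, match="events"):
            fit_cox(_design([1, 2, 3], [0, 0, 0], [0, 1, 0]))

    def test_constant_covariate_rejected(self):
        with pytest.raises(CoxFitError, match="constant"):
            fit_cox(_design([1, 2, 3, 4], [1, 1, 1, 0], [2, 2, 2, 2]))


class TestDesignMatrix:
    def _clinical(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "os_time_years": rng.exponential(2, n) + 0.01,
                "os_event": rng.integers(0, 2, n),
                "mirv_max_distance": rng.normal(5, 2, n),
                "age": rng.normal(60, 10, n),
                "performance_status": rng.integers(0, 3, n).astype(float),
                "baseline_total": rng.lognormal(9, 1, n),
                "histology": rng.choice(
                    ["Leiomyosarcoma", "Liposarcoma", "UPS", "Other"], n
                ),
                "recist": rng.choice(["PR", "SD", "PD"], n),
            }
        )

    def test_reference_levels_have_no_column(self):
        X = build_design_matrix(self._clinical(), "mirv_max_distance")
        assert "hist_Other" not in X.columns
        assert "recist_SD" not in X.columns
        assert {"hist_Leiomyosarcoma", "hist_Liposarcoma", "hist_UPS"} <= set(X.columns)

    def test_interaction_terms_are_products(self):
        df = self._clinical(seed=1)
        X = build_design_matrix(df, "mirv_max_distance", interaction=True)
        lms = (df["histology"] == "Leiomyosarcoma").astype(float)
        expected = (lms * df["mirv_max_distance"]).to_numpy()
        assert np.allclose(
            X["mirv_max_distance_x_hist_Leiomyosarcoma"].to_numpy(), expected
        )

    def test_full_model_fits(self):
        X = build_design_matrix(self._clinical(seed=2, n=120), "mirv_max_distance",
                                interaction=True)
        res = fit_cox(X)
        assert set(res.summary["covariate"]) == set(X.columns) - {
            "os_time_years", "os_event"
        }
        assert (res.summary["ci_lower"] <= res.summary["ci_upper"]).all()


class TestDichotomize:
    def test_even_split(self):
        g = dichotomize(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert g.tolist() == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        g = dichotomize(pd.Series([1.0, 1.0, 2.0]))
        assert g.tolist() == ["low", "low", "high"]

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(pd.Series([2.0, 2.0, 2.0]))


def hand_logrank(times, events, groups):
    """O-E over hypergeometric variance at each distinct event time."""
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    labels = sorted(df["g"].unique())
    O_minus_E, V = 0.0, 0.0
    for t in sorted(df.loc[df["e"] == 1, "t"].unique()):
        at_risk = df["t"] >= t
        n = at_risk.sum()
        n1 = (at_risk & (df["g"] == labels[0])).sum()
        d = ((df["t"] == t) & (df["e"] == 1)).sum()
        d1 = ((df["t"] == t) & (df["e"] == 1) & (df["g"] == labels[0])).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


class TestKMLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 0, 1, 1, 0]
        groups = ["a", "a", "a", "b", "b", "b"]
        res = km_logrank(times, events, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_hand_example(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 0, 1]
        groups = ["a", "b", "a", "b", "a", "b"]
        res = km_logrank(times, events, groups)
        assert res.statistic == pytest.approx(hand_logrank(times, events, groups), abs=1e-10)

    def test_km_curves_start_at_one_and_decrease(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(2, 40)
        events = rng.integers(0, 2, 40)
        groups = ["a"] * 20 + ["b"] * 20
        res = km_logrank(times, events, groups)
        for curve in res.curves.values():
            assert curve["survival"].iloc[0] == pytest.approx(1.0)
            assert (np.diff(curve["survival"]) <= 1e-12).all()
            assert curve["at_risk"].iloc[0] == 20

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(4)
        t_a = rng.exponential(1.0, 100)
        t_b = rng.exponential(3.0, 100)
        res = km_logrank(
            np.concatenate([t_a, t_b]),
            np.ones(200, int),
            ["a"] * 100 + ["b"] * 100,
        )
        assert res.p < 0.001

    def test_wrong_group_count_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3], [1, 1, 1], ["a", "a", "a"])


class TestSubgroupAnalysis:
    def _cohort(self, n=240, beta=1.5, seed=0):
        rng = np.random.default_rng(seed)
        hist = rng.choice(["Leiomyosarcoma", "Other"], n, p=[0.5, 0.5])
        mirv = rng.uniform(0, 2, n)
        hazard = 0.5 * np.exp(beta * mirv * (hist == "Leiomyosarcoma"))
        t = rng.exponential(1 / hazard)
        c = rng.exponential(6.0, n)
        return pd.DataFrame(
            {
                "os_time_years": np.minimum(t, c),
                "os_event": (t <= c).astype(int),
                "mirv_max_distance": mirv,
                "histology": hist,
            }
        )

    def test_effect_detected_only_in_affected_stratum(self):
        res = subgroup_analysis(self._cohort(), "mirv_max_distance")
        assert res["Leiomyosarcoma"].p < 0.05
        assert res["Other"].p > res["Leiomyosarcoma"].p

    def test_small_stratum_skipped(self):
        df = self._cohort(n=60)
        df.loc[df.index[:3], "histology"] = "UPS"
        df = df[(df["histology"] != "UPS") | (df.index < df.index[3])]
        res = subgroup_analysis(df, "mirv_max_distance", min_size=20)
        assert "UPS" not in res

    def test_single_level_equals_full_cohort(self):
        df = self._cohort(n=80)
        df["histology"] = "Other"
        res = subgroup_analysis(df, "mirv_max_distance")
        groups = dichotomize(df["mirv_max_distance"])
        full = km_logrank(df["os_time_years"], df["os_event"], groups)
        assert res["Other"].statistic == pytest.approx(full.statistic)
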