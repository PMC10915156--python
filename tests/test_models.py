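import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from dyadlink import (
    GLMFit,
    association_table,
    describe_by_group,
    fit_linear,
    fit_logistic,
    tjur_r2,
    wald_interaction_test,
)
from dyadlink.models import PerfectSeparationError, RankDeficientError


class TestFitLinear:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 10, 50)
        t = pd.DataFrame({"x": x, "y": 2.5 * x - 1.0})
        fit = fit_linear(t, "y", ["x"])
        assert fit.coef["x"] == pytest.approx(2.5, abs=1e-10)
        assert fit.coef["const"] == pytest.approx(-1.0, abs=1e-9)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_intercept_only_is_sample_mean(self):
        t = pd.DataFrame({"y": [1.0, 2.0, 4.0, 9.0]})
        fit = fit_linear(t, "y", [])
        assert fit.coef["const"] == pytest.approx(4.0)

    def test_planted_effect_recovered_within_3_se(self):
        rng = np.random.default_rng(0)
        n = 100_000
        a = (rng.random(n) < 0.3).astype(float)
        y = 1.76 * a + rng.normal(0, 5.0, n)
        fit = fit_linear(pd.DataFrame({"a": a, "y": y}), "y", ["a"])
        assert abs(fit.coef["a"] - 1.76) < 3 * fit.se()["a"]

    def test_rank_deficiency_names_column(self):
        t = pd.DataFrame({"y": [1.0, 2, 3, 4], "x": [1.0, 2, 3, 4]})
        t["x2"] = 2 * t["x"]
        with pytest.raises(RankDeficientError, match="x2"):
            fit_linear(t, "y", ["x", "x2"])

    def test_rows_with_missing_values_dropped(self):
        t = pd.DataFrame({"y": [1.0, 2, np.nan, 4], "x": [0.0, 1, 2, 3]})
        assert fit_linear(t, "y", ["x"]).n == 3


class TestFitLogistic:
    def test_binary_predictor_equals_cross_ratio(self, marital_by_loneliness):
        """On the published 2x2 marital-by-loneliness counts the fitted
        coefficient is the closed-form log cross-ratio, -1.010."""
        fit = fit_logistic(marital_by_loneliness, "lonely", ["marital"])
        oracle = math.log((178 * 126) / (581 * 106))
        assert fit.coef["marital"] == pytest.approx(oracle, abs=1e-6)
        assert fit.coef["marital"] == pytest.approx(-1.010, abs=5e-4)

    def test_cross_ratio_equivalence_random_tables(self):
        """Logistic slope on one binary predictor equals the 2x2
        log-odds cross-ratio exactly (small random tables)."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            cells = rng.integers(5, 60, size=4)
            rows = []
            for (x, y), n in zip([(0, 0), (0, 1), (1, 0), (1, 1)], cells):
                rows += [{"x": float(x), "y": float(y)}] * int(n)
            t = pd.DataFrame(rows)
            fit = fit_logistic(t, "y", ["x"])
            a, b, c, d = cells
            oracle = math.log((d * a) / (b * c))
            assert fit.coef["x"] == pytest.approx(oracle, abs=1e-6)

    def test_intercept_only_prevalence(self):
        y = np.zeros(100)
        y[:29] = 1.0
        fit = fit_logistic(pd.DataFrame({"y": y}), "y", [])
        assert fit.coef["const"] == pytest.approx(float(logit(0.29)), abs=1e-6)

    def test_constant_predictor_rank_deficient(self):
        t = pd.DataFrame({"y": [0.0, 1, 0, 1], "x": [2.0, 2, 2, 2]})
        with pytest.raises(RankDeficientError):
            fit_logistic(t, "y", ["x"])

    def test_perfect_separation_detected(self):
        t = pd.DataFrame({"x": np.arange(20.0)})
        t["y"] = (t["x"] >= 10).astype(float)
        with pytest.raises(PerfectSeparationError):
            fit_logistic(t, "y", ["x"])

    def test_single_class_rejected(self):
        t = pd.DataFrame({"y": [1.0, 1, 1, 1], "x": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(t, "y", ["x"])

    def test_association_table_or_scale(self, marital_by_loneliness):
        fit = fit_logistic(marital_by_loneliness, "lonely", ["marital"])
        tab = association_table(fit).set_index("term")
        row = tab.loc["marital"]
        assert row["estimate"] == pytest.approx(math.exp(fit.coef["marital"]))
        assert row["ci_lower"] < row["estimate"] < row["ci_upper"]
        assert (tab["estimate"] > 0).all()


class TestWaldInteraction:
    def _fit_with_coef(self, coef, se):
        return GLMFit(
            kind="logistic",
            coef=pd.Series({"const": 0.0, "axm": coef}),
            vcov=pd.DataFrame(
                [[0.01, 0.0], [0.0, se**2]], index=["const", "axm"],
                columns=["const", "axm"],
            ),
            n=100,
        )

    def test_zero_coefficient_p_one(self):
        assert wald_interaction_test(self._fit_with_coef(0.0, 0.5), "axm") == 1.0

    def test_1p96_se_p_05(self):
        p = wald_interaction_test(self._fit_with_coef(1.96 * 0.5, 0.5), "axm")
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_absent_term_rejected(self):
        with pytest.raises(KeyError):
            wald_interaction_test(self._fit_with_coef(0.0, 0.5), "nope")


class TestTjurR2:
    def _manual_fit(self, fitted, response):
        return GLMFit(
            kind="logistic",
            coef=pd.Series({"const": 0.0}),
            vcov=pd.DataFrame([[1.0]], index=["const"], columns=["const"]),
            n=len(fitted),
            fitted=np.asarray(fitted, dtype=float),
            response=np.asarray(response, dtype=float),
        )

    def test_perfect_model_is_one(self):
        fit = self._manual_fit([1, 1, 0, 0], [1, 1, 0, 0])
        assert tjur_r2(fit) == 1.0

    def test_intercept_only_is_zero(self):
        y = np.array([1.0, 1, 0, 0, 0, 0])
        t = pd.DataFrame({"y": y})
        fit = fit_logistic(t, "y", [])
        assert tjur_r2(fit) == pytest.approx(0.0, abs=1e-10)

    def test_toy_six_rows_direct_average(self):
        # cases fitted at (.9, .6, .7) mean .7333; controls (.2, .4, .3)
        # mean .3 -> Tjur R2 = 0.43333
        fit = self._manual_fit([0.9, 0.6, 0.7, 0.2, 0.4, 0.3], [1, 1, 1, 0, 0, 0])
        assert tjur_r2(fit) == pytest.approx(13 / 30)

    def test_bounded_for_fitted_models(self, scored_table):
        from dyadlink import schema

        sub = scored_table.dropna(
            subset=[schema.OUTCOME, "g0_parent_lonely_class", "income"]
        )
        fit = fit_logistic(sub, schema.OUTCOME, ["g0_parent_lonely_class", "income"])
        assert 0.0 <= tjur_r2(fit) <= 1.0


class TestDescribeByGroup:
    def test_identical_groups_p_one(self):
        half = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        t = pd.concat(
            [half.assign(g=0.0), half.assign(g=1.0)], ignore_index=True
        )
        out = describe_by_group(t, "g", continuous=["x"])
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_marital_split_highly_significant(self, marital_by_loneliness):
        out = describe_by_group(
            marital_by_loneliness, "lonely", continuous=[], categorical=["marital"]
        )
        row = out.set_index("variable").loc["marital"]
        assert row["p_value"] < 0.001
        assert row["group0_value"] == pytest.approx(82.2, abs=0.05)
        assert row["group1_value"] == pytest.approx(62.7, abs=0.05)

    def test_missing_counts_reported(self):
        t = pd.DataFrame(
            {"g": [0.0, 0, 1, 1, 1, 0], "x": [1.0, np.nan, 2, np.nan, 3, 4]}
        )
        out = describe_by_group(t, "g", continuous=["x"])
        assert out.loc[0, "missing0"] == 1 and out.loc[0, "missing1"] == 1

    def test_non_binary_group_rejected(self):
        t = pd.DataFrame({"g": [0.0, 1, 2], "x": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            describe_by_group(t, "g", continuous=["x"])
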