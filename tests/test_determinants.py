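"""Correlations, stratified summaries and additive-model fits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from schoolenv import fit_determinants, pearson_ci, stratified_summary
from schoolenv.determinants import correlation_strength
from schoolenv.synthetic import generate_determinant_table


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.strength == "strong"

    def test_independent_data_near_zero_with_coverage(self):
        """|r| small and CI covers 0 about 95% of the time under the null."""
        rng = np.random.default_rng(1)
        covered = 0
        reps = 200
        for _ in range(reps):
            x, y = rng.normal(size=(2, 1000))
            res = pearson_ci(x, y)
            assert abs(res.r) < 0.15
            covered += res.ci_low <= 0 <= res.ci_high
        assert 0.90 <= covered / reps <= 0.99

    @pytest.mark.parametrize(
        "r, label",
        [(0.29, "weak"), (-0.29, "weak"), (0.30, "moderate"), (0.46, "moderate"),
         (-0.46, "moderate"), (0.50, "moderate"), (0.51, "strong"), (-0.9, "strong")],
    )
    def test_strength_labels(self, r, label):
        assert correlation_strength(r) == label

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (10, 100, 1000):
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            res = pearson_ci(x, y)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            pearson_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            pearson_ci([1, 2], [2, 3])


class TestStratifiedSummary:
    def test_percentiles_by_hand(self):
        values = {f"s{i}": float(v) for i, v in enumerate([1, 2, 3, 4, 5])}
        strata = {s: "all" for s in values}
        out = stratified_summary(values, strata).iloc[0]
        assert out["median"] == 3 and out["iqr_low"] == 2 and out["iqr_high"] == 4
        assert out["min"] == 1 and out["max"] == 5 and out["n"] == 5

    def test_single_value_degenerate(self):
        out = stratified_summary({"s": 7.0}, {"s": "x"}).iloc[0]
        assert out["median"] == out["iqr_low"] == out["iqr_high"] == 7.0
        assert out["min"] == out["max"] == 7.0

    def test_constant_shift_equivariance(self):
        rng = np.random.default_rng(3)
        base = {f"a{i}": float(v) for i, v in enumerate(rng.normal(size=9))}
        shifted = {f"b{i}": v + 2.5 for i, (_k, v) in enumerate(base.items())}
        values = {**base, **shifted}
        strata = {k: ("A" if k.startswith("a") else "B") for k in values}
        out = stratified_summary(values, strata).set_index("stratum")
        assert out.loc["B", "median"] - out.loc["A", "median"] == pytest.approx(2.5)

    def test_empty_stratum_omitted_with_warning(self):
        with pytest.warns(UserWarning):
            out = stratified_summary({"a": 1.0}, {"a": "x", "b": "y"})
        assert list(out["stratum"]) == ["x"]


class TestAdditiveModel:
    def test_pure_linear_limit_matches_ols(self):
        """With constant meteorology the GAM reduces to OLS exactly."""
        table, _ = generate_determinant_table(
            n_schools=90, effects={"commercial_market": 0.3, "ndvi": -1.5},
            noise_sd=0.15, seed=4, constant_meteorology=True,
        )
        res = fit_determinants(table, "ln_pm25")
        from schoolenv.determinants import _design

        X = sm.add_constant(_design(table), has_constant="add")
        ols = sm.OLS(np.log(table["pm25"]), X).fit()
        for name, (est, lo, hi) in res.coefficients.items():
            assert est == pytest.approx(ols.params[name], abs=1e-6)
        assert res.spline_edf == {}

    def test_known_market_effect_coverage(self):
        """95% CI covers the true +0.3 ln-scale market effect in ≥90% of 50 replicates."""
        hits = 0
        for rep in range(50):
            table, effects = generate_determinant_table(
                n_schools=90, effects={"commercial_market": 0.3}, noise_sd=0.2, seed=1000 + rep
            )
            res = fit_determinants(table, "ln_pm25")
            est, lo, hi = res.coefficients["commercial_market"]
            hits += lo <= effects["commercial_market"] <= hi
        assert hits >= 45

    def test_pure_spline_response_yields_null_linear_cis(self):
        """Response driven only by smoothed temperature: the linear CIs cover
        their true value of 0 at close to the nominal 95% rate."""
        cover, total = 0, 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            table, _ = generate_determinant_table(
                n_schools=120, effects={}, noise_sd=0.0, seed=200 + rep
            )
            eta = 0.03 * (table["temperature"] - 28.0) ** 2 + rng.normal(0, 0.1, len(table))
            table["pm25"] = np.exp(3.0 + eta)
            res = fit_determinants(table, "ln_pm25")
            for _est, lo, hi in res.coefficients.values():
                cover += lo <= 0 <= hi
                total += 1
        assert cover / total >= 0.85

    def test_noiseless_linear_response_explains_all_deviance(self):
        table, _ = generate_determinant_table(
            n_schools=90, effects={"commercial_market": 0.4, "ses_index": -0.2},
            noise_sd=0.0, seed=8, constant_meteorology=True,
        )
        res = fit_determinants(table, "ln_pm25")
        assert res.deviance_explained == pytest.approx(100.0, abs=1e-6)

    def test_spline_edf_and_pvalues_reported(self):
        table, _ = generate_determinant_table(n_schools=90, seed=9)
        res = fit_determinants(table, "ln_pm25")
        assert set(res.spline_edf) == {"temperature", "rh", "rain"}
        for edf, p in res.spline_edf.values():
            assert edf > 0 and 0 <= p <= 1
        assert 0 <= res.deviance_explained <= 100

    def test_rank_deficiency_names_collinear_predictors(self):
        table, _ = generate_determinant_table(n_schools=60, seed=10)
        table["dist_secondary_road"] = 2.0 * table["dist_major_road"]
        with pytest.raises(ValueError, match="dist_"):
            fit_determinants(table, "ln_pm25")

    def test_missing_values_rejected(self):
        table, _ = generate_determinant_table(n_schools=30, seed=11)
        table.loc[3, "ndvi"] = np.nan
        with pytest.raises(ValueError, match="ndvi"):
            fit_determinants(table, "ln_pm25")

    def test_unknown_response_rejected(self):
        table, _ = generate_determinant_table(n_schools=30, seed=12)
        with pytest.raises(ValueError):
            fit_determinants(table, "sqrt_pm25")
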