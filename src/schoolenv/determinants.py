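"""Determinant analysis: correlations, stratified summaries, additive models.

Pollutant levels (annual-equivalent PM2.5, BC absorbance, weekly noise)
are related to school and neighborhood characteristics three ways:
Pearson correlations with Fisher-z confidence intervals and
weak/moderate/strong labels; median/IQR summaries stratified by school
type, district, surface or SES split; and generalized additive models
with linear terms for the categorical/spatial predictors and penalized
spline smoothers for weekly temperature, relative humidity and rain.
PM2.5 and BC are right-skewed and modelled on the natural-log scale, so
coefficients are approximately proportional effects; noise is modelled
in dBA untransformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

#: |r| cut-points for correlation strength labels.
WEAK_BELOW = 0.3
STRONG_ABOVE = 0.5

#: Linear predictors with their reference categories ("—" rows of the model table).
CATEGORICAL_TERMS: dict[str, tuple[str, tuple[str, ...]]] = {
    "district": ("other", ("TMA", "AMA")),
    "commercial": ("none", ("market", "other_commercial")),
    "surface": ("unpaved", ("paved",)),
    "school_type": ("private", ("public",)),
    "season": ("non-Harmattan", ("Harmattan",)),
}
CONTINUOUS_TERMS = ("dist_major_road", "dist_secondary_road", "ndvi", "ses_index")
SMOOTH_TERMS = ("temperature", "rh", "rain")

RESPONSES = ("ln_pm25", "ln_bc", "leq_wk")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    strength: str


def correlation_strength(r: float) -> str:
    """Label |r| as weak (<0.3), moderate (0.3–0.5) or strong (>0.5)."""
    a = abs(r)
    if a < WEAK_BELOW:
        return "weak"
    if a <= STRONG_ABOVE:
        return "moderate"
    return "strong"


def pearson_ci(x: Sequence[float], y: Sequence[float], level: float = 0.95) -> CorrelationResult:
    """Sample Pearson r with a Fisher z-transform confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"need n ≥ 4 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(stats.pearsonr(x, y).statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationResult(r=r, ci_low=float(lo), ci_high=float(hi), n=n,
                             strength=correlation_strength(r))


def stratified_summary(
    values: Mapping[str, float], strata: Mapping[str, str]
) -> pd.DataFrame:
    """Median, IQR (linear-interpolated percentiles), range and n per stratum.

    Schools present in ``strata`` but absent from ``values`` define an
    empty stratum, which is omitted with a warning.
    """
    groups: dict[str, list[float]] = {}
    for school, label in strata.items():
        if school in values:
            groups.setdefault(label, []).append(values[school])
        else:
            groups.setdefault(label, groups.get(label, []))
    rows = []
    for label in sorted(groups):
        vals = groups[label]
        if not vals:
            warnings.warn(f"stratum {label!r} has no values; omitted", stacklevel=2)
            continue
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        rows.append(
            {
                "stratum": label,
                "n": len(vals),
                "median": q50,
                "iqr_low": q25,
                "iqr_high": q75,
                "min": min(vals),
                "max": max(vals),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DeterminantModelResult:
    """Additive-model fit for one response.

    ``coefficients`` maps each non-reference linear predictor to
    (estimate, ci_low, ci_high); ``spline_edf`` maps each smoother to
    (effective degrees of freedom, p-value); ``deviance_explained`` is
    the percent of null deviance explained.
    """

    response: str
    coefficients: dict[str, tuple[float, float, float]]
    spline_edf: dict[str, tuple[float, float]]
    deviance_explained: float
    n: int


def _design(table: pd.DataFrame) -> pd.DataFrame:
    """Linear design with treatment coding against the fixed reference categories."""
    X = pd.DataFrame(index=table.index)
    X["district_TMA"] = (table["district"] == "TMA").astype(float)
    X["district_AMA"] = (table["district"] == "AMA").astype(float)
    X["dist_major_road"] = table["dist_major_road"].astype(float)
    X["dist_secondary_road"] = table["dist_secondary_road"].astype(float)
    X["commercial_market"] = (table["commercial"] == "market").astype(float)
    X["commercial_other"] = (table["commercial"] == "other").astype(float)
    X["ndvi"] = table["ndvi"].astype(float)
    X["ses_index"] = table["ses_index"].astype(float)
    X["surface_paved"] = (table["surface"] == "paved").astype(float)
    X["school_type_public"] = (table["school_type"] == "public").astype(float)
    X["season_Harmattan"] = (table["season"] == "Harmattan").astype(float)
    return X


def _response_vector(table: pd.DataFrame, response: str) -> np.ndarray:
    if response.startswith("ln_"):
        col = response[3:]
        vals = table[col].astype(float).to_numpy()
        if (vals <= 0).any():
            raise ValueError(f"{col} must be positive for log transform")
        return np.log(vals)
    return table[response].astype(float).to_numpy()


def _check_rank(X: pd.DataFrame) -> None:
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the columns involved: those whose removal restores full rank
        culprits = []
        for col in X.columns:
            sub = Xc.drop(columns=[col])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                culprits.append(col)
        raise ValueError(f"design is rank deficient; collinear predictors: {culprits}")


def fit_determinants(
    table: pd.DataFrame,
    response: str,
    spline_df: int = 6,
    alpha: float | Sequence[float] = 1.0,
    gcv: bool = False,
) -> DeterminantModelResult:
    """Fit a Gaussian additive model of one pollutant on the school predictors.

    Linear terms: district (ref: other GAMA districts), distances to
    major/secondary roads, commercial activity (ref: none), NDVI, SES
    index, schoolyard surface (ref: unpaved), school type (ref: private)
    and season (ref: non-Harmattan).  Weekly temperature, relative
    humidity and rain enter through penalized cubic B-spline smoothers;
    ``gcv=True`` selects the penalty weights by generalized
    cross-validation, otherwise ``alpha`` is used as given.  A smoother
    whose input is (near-)constant carries no information and is dropped,
    so the model degenerates gracefully to an ordinary linear fit.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}, got {response!r}")
    used_cols = (
        ["district", "commercial", "surface", "school_type", "season"]
        + list(CONTINUOUS_TERMS)
        + list(SMOOTH_TERMS)
    )
    if table[used_cols].isna().any().any():
        missing = table[used_cols].isna().any()
        raise ValueError(f"missing values in predictors: {list(missing[missing].index)}")

    y = _response_vector(table, response)
    X = _design(table)
    _check_rank(X)

    smooth_active = [
        c for c in SMOOTH_TERMS if np.ptp(table[c].astype(float).to_numpy()) > 1e-10
    ]
    exog_linear = sm.add_constant(X, has_constant="add")

    if not smooth_active:
        res = sm.GLM(y, exog_linear).fit()
        edf: dict[str, tuple[float, float]] = {}
        params, ci = res.params, res.conf_int()
    else:
        smoother = BSplines(
            table[smooth_active].astype(float).to_numpy(),
            df=[spline_df] * len(smooth_active),
            degree=[3] * len(smooth_active),
            variable_names=smooth_active,
        )
        alphas = (
            list(np.broadcast_to(np.asarray(alpha, dtype=float), len(smooth_active)))
        )
        gam = GLMGam(y, exog=exog_linear, smoother=smoother, alpha=alphas)
        res = gam.fit()
        if gcv:
            alphas = list(gam.select_penweight()[0])
            gam = GLMGam(y, exog=exog_linear, smoother=smoother, alpha=alphas)
            res = gam.fit()
        params, ci = res.params, res.conf_int()
        k_lin = exog_linear.shape[1]
        edf = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            for i, name in enumerate(smooth_active):
                cols = k_lin + np.asarray(smoother.mask[i]).nonzero()[0]
                term_edf = float(np.sum(res.edf[cols]))
                pval = float(np.squeeze(res.test_significance(i).pvalue))
                edf[name] = (term_edf, pval)

    params = np.asarray(params, dtype=float)
    ci = np.asarray(ci, dtype=float)
    coef = {}
    for j, name in enumerate(exog_linear.columns):
        if name == "const":
            continue
        coef[name] = (float(params[j]), float(ci[j, 0]), float(ci[j, 1]))

    null = sm.GLM(y, np.ones_like(y)).fit()
    dev_expl = 100.0 * (1.0 - res.deviance / null.deviance)
    return DeterminantModelResult(
        response=response,
        coefficients=coef,
        spline_edf=edf,
        deviance_explained=float(dev_expl),
        n=len(y),
    )
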