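"""Determinants of school pollution: correlations, strata and additive models.

Builds the merged one-row-per-school table (annual-equivalent PM2.5 and
BC, weekly noise, covariates, weekly meteorology), then reports Pearson
correlations of pollutants with NDVI / road distance / SES, stratified
median-IQR summaries, and generalized additive model fits (penalized
spline smoothers for temperature, relative humidity and rain; PM2.5 and
BC on the natural-log scale).  Schools whose filter failed QC have no
BC value and drop out of the BC model only.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_study, parser

from schoolenv import fit_determinants, pearson_ci, ses_split, stratified_summary
from schoolenv.pipeline import run_pipeline


def model_frame(res) -> pd.DataFrame:
    rows = [
        {"term": name, "estimate": est, "ci_low": lo, "ci_high": hi, "kind": "linear"}
        for name, (est, lo, hi) in res.coefficients.items()
    ]
    rows += [
        {"term": f"s({name})", "estimate": edf, "ci_low": np.nan, "ci_high": np.nan,
         "kind": "smooth_edf", "p_value": p}
        for name, (edf, p) in res.spline_edf.items()
    ]
    df = pd.DataFrame(rows)
    df["deviance_explained"] = res.deviance_explained
    return df


def main() -> None:
    args = parser(__doc__).parse_args()
    bundle, _truth = load_study(args.seed)
    pipe = run_pipeline(bundle)
    merged = pipe.merged

    RESULTS.mkdir(parents=True, exist_ok=True)
    merged.to_csv(RESULTS / "merged_school_table.csv", index=False)

    # --- correlations -----------------------------------------------------
    corr_rows = []
    pairs = [
        ("ndvi", "pm25"), ("ndvi", "bc"), ("ndvi", "l_day_school"),
        ("dist_major_road", "pm25"), ("dist_major_road", "bc"),
        ("dist_major_road", "l_day_school"),
        ("ses_index", "pm25"), ("ses_index", "bc"), ("ses_index", "l_day_school"),
    ]
    for x, y in pairs:
        sub = merged[[x, y]].dropna()
        r = pearson_ci(sub[x], sub[y])
        corr_rows.append({"x": x, "y": y, "r": r.r, "ci_low": r.ci_low,
                          "ci_high": r.ci_high, "n": r.n, "strength": r.strength})
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(RESULTS / "correlations.csv", index=False)

    # --- stratified summaries --------------------------------------------
    values = dict(zip(merged.school_id, merged.pm25))
    strata_tables = []
    for by in ("school_type", "district", "surface"):
        strata = dict(zip(merged.school_id, merged[by]))
        t = stratified_summary(values, strata)
        t.insert(0, "stratified_by", by)
        strata_tables.append(t)
    ses = ses_split(dict(zip(merged.school_id, merged.ses_index)))
    t = stratified_summary(values, ses)
    t.insert(0, "stratified_by", "ses_median_split")
    strata_tables.append(t)
    strat = pd.concat(strata_tables, ignore_index=True)
    strat.to_csv(RESULTS / "stratified_pm25.csv", index=False)

    # --- additive models --------------------------------------------------
    frames = []
    for response in ("ln_pm25", "ln_bc", "leq_wk"):
        table = merged if response != "ln_bc" else merged.dropna(subset=["bc"])
        res = fit_determinants(table, response)
        mf = model_frame(res)
        mf.insert(0, "response", response)
        frames.append(mf)
        print(f"{response}: deviance explained {res.deviance_explained:.0f}% "
              f"(n={res.n}).")
    pd.concat(frames, ignore_index=True).to_csv(RESULTS / "determinant_models.csv", index=False)

    print("\nKey correlations:")
    for row in corr.itertuples():
        print(f"  {row.x} vs {row.y}: r = {row.r:+.2f} "
              f"[{row.ci_low:+.2f}, {row.ci_high:+.2f}] ({row.strength})")
    med = strat[strat.stratified_by == "ses_median_split"].set_index("stratum")["median"]
    if {"below_median", "above_median"} <= set(med.index):
        print(f"\nMedian annual PM2.5: {med['below_median']:.1f} µg/m³ below-median SES "
              f"vs {med['above_median']:.1f} above.")
    print(f"Wrote correlations.csv, stratified_pm25.csv, determinant_models.csv under {RESULTS}/.")


if __name__ == "__main__":
    main()
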