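"""End-to-end orchestration of the exposure pipeline on a study bundle.

Stage order mirrors the field workflow: filter QC and gravimetric
concentrations → collocation CFs and season means → correction (or
seasonal imputation) of continuous series → weekly TAFs and
annual-equivalent concentrations (full week and school hours) → noise
metrics → annoyance scoring → merged determinant table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annoyance as ann
from . import noise as nz
from . import pm_calibration as cal
from . import temporal as tmp
from .synthetic import StudyBundle


@dataclass
class PipelineResult:
    calibration: pd.DataFrame  # per school: QC, gravimetric, CF used
    seasonal_cfs: dict[str, cal.CorrectionFactor]
    tafs: pd.DataFrame  # per week: TAF for pm25 and bc
    annual: pd.DataFrame  # per school: annual equivalents
    noise: pd.DataFrame  # per school: l_day_school, leq_wk, ir
    ha_by_school: pd.DataFrame  # per school/source HA metrics
    exposure_response: ann.ExposureResponse
    merged: pd.DataFrame  # school table for determinant models


def calibrate(bundle: StudyBundle) -> tuple[pd.DataFrame, dict[str, cal.CorrectionFactor]]:
    """QC every filter, compute collocation CFs where valid, pool by season."""
    rows = []
    cfs = []
    for school, dep in sorted(bundle.deployments.items()):
        s = dep.filter_sample
        qc = cal.qc_filter_sample(s)
        grav = cal.gravimetric_concentration(s) if qc.valid else np.nan
        bc = cal.bc_absorption_coefficient(s) if qc.valid else np.nan
        cf_value = np.nan
        if qc.valid:
            cf = cal.collocation_cf(grav, dep.continuous_pm, season=dep.season)
            cfs.append(cf)
            cf_value = cf.value
        rows.append(
            {
                "school_id": school,
                "week": dep.week,
                "season": dep.season,
                "qc_valid": qc.valid,
                "qc_reasons": ";".join(qc.reasons),
                "gravimetric_pm25": grav,
                "bc_absorbance": bc,
                "collocation_cf": cf_value,
            }
        )
    return pd.DataFrame(rows), cal.seasonal_mean_cf(cfs)


def corrected_series(
    bundle: StudyBundle,
    calibration: pd.DataFrame,
    seasonal_cfs: dict[str, cal.CorrectionFactor],
) -> dict[str, "nz.MinuteSeries"]:
    """CF-corrected continuous PM series per school.

    Schools with a valid collocation use their own CF; schools whose
    filter failed QC fall back on the pooled seasonal mean CF.
    """
    cal_by_school = calibration.set_index("school_id")
    out = {}
    for school, dep in bundle.deployments.items():
        row = cal_by_school.loc[school]
        if row["qc_valid"]:
            cf = cal.CorrectionFactor(value=float(row["collocation_cf"]), season=dep.season)
        else:
            cf = seasonal_cfs[dep.season]
        out[school] = cal.apply_cf(dep.continuous_pm, cf)
    return out


def adjust(
    bundle: StudyBundle,
    calibration: pd.DataFrame,
    corrected: dict[str, "nz.MinuteSeries"],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly TAFs and per-school annual equivalents.

    The weekly PM2.5 mean is the gravimetric concentration where the
    filter passed QC, otherwise the corrected continuous mean; the
    school-hours metric always comes from the corrected continuous
    series and is adjusted by the same weekly TAF.
    """
    taf_rows = [
        {
            "week": w,
            "taf_pm25": tmp.weekly_taf(bundle.fixed_pm_network, w).value,
            "taf_bc": tmp.weekly_taf(bundle.fixed_bc_network, w).value,
        }
        for w in bundle.fixed_pm_network.weeks
    ]
    tafs = pd.DataFrame(taf_rows)

    cal_by_school = calibration.set_index("school_id")
    rows = []
    for school, dep in sorted(bundle.deployments.items()):
        row = cal_by_school.loc[school]
        if row["qc_valid"]:
            week_mean = float(row["gravimetric_pm25"])
            bc_week = float(row["bc_absorbance"])
        else:
            week_mean = corrected[school].mean()
            bc_week = np.nan
        sh_mean = tmp.school_hours_mean(corrected[school])
        ae = tmp.annualize_school(
            school_id=school,
            week=dep.week,
            pm_network=bundle.fixed_pm_network,
            pm_week_mean=week_mean,
            bc_network=bundle.fixed_bc_network,
            bc_week_value=None if np.isnan(bc_week) else bc_week,
            pm_school_hours_mean=sh_mean,
        )
        rows.append(
            {
                "school_id": school,
                "week": dep.week,
                "season": dep.season,
                "measured_week_pm25": week_mean,
                "pm25_annual": ae.pm25,
                "bc_annual": ae.bc if ae.bc is not None else np.nan,
                "pm25_school_hours_annual": ae.pm25_school_hours,
            }
        )
    return tafs, pd.DataFrame(rows)


def noise_metrics(bundle: StudyBundle) -> pd.DataFrame:
    rows = []
    for school, dep in sorted(bundle.deployments.items()):
        res = nz.noise_summary(dep.sound)
        rows.append(
            {
                "school_id": school,
                "l_day_school": res.l_day_school,
                "leq_wk": res.leq_wk,
                "ir": res.ir,
                "minutes_l_day": res.minutes_used["l_day_school"],
            }
        )
    return pd.DataFrame(rows)


def annoyance_metrics(bundle: StudyBundle, noise_table: pd.DataFrame) -> tuple[pd.DataFrame, ann.ExposureResponse]:
    rows = []
    for school in sorted(bundle.deployments):
        rs = [r for r in bundle.surveys if r.school_id == school]
        for source in ann.NOISE_SOURCES:
            src = [r for r in rs if r.source == source]
            if not src:
                continue
            res = ann.ha_result(src)
            rows.append(
                {
                    "school_id": school,
                    "source": source,
                    "ha_n": res.ha_n,
                    "ha_v": res.ha_v,
                    "ha_vw": res.ha_vw,
                    "n": res.n_respondents,
                }
            )
    levels = dict(zip(noise_table["school_id"], noise_table["l_day_school"]))
    er = ann.exposure_response(levels, bundle.surveys, source="road_traffic")
    return pd.DataFrame(rows), er


def merged_table(
    bundle: StudyBundle, annual: pd.DataFrame, noise_table: pd.DataFrame
) -> pd.DataFrame:
    """One row per school: pollutants + covariates + weekly meteorology."""
    df = (
        annual.merge(noise_table, on="school_id")
        .merge(bundle.covariates.drop(columns=["season", "week"]), on="school_id")
        .merge(bundle.meteorology, on="week")
    )
    return df.rename(columns={"pm25_annual": "pm25", "bc_annual": "bc"})


def run_pipeline(bundle: StudyBundle) -> PipelineResult:
    calibration, seasonal_cfs = calibrate(bundle)
    corrected = corrected_series(bundle, calibration, seasonal_cfs)
    tafs, annual = adjust(bundle, calibration, corrected)
    noise_table = noise_metrics(bundle)
    ha, er = annoyance_metrics(bundle, noise_table)
    merged = merged_table(bundle, annual, noise_table)
    return PipelineResult(
        calibration=calibration,
        seasonal_cfs=seasonal_cfs,
        tafs=tafs,
        annual=annual,
        noise=noise_table,
        ha_by_school=ha,
        exposure_response=er,
        merged=merged,
    )
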