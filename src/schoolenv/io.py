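"""CSV interchange for every pipeline table.

All formats are plain CSV with ISO-8601 minute timestamps:

- minute series: ``site_id, timestamp, value, kind``
- filter log: ``school_id, week, pre_mass_ug, post_mass_ug,
  mean_flow_lpm, runtime_min, season, filter_area_m2,
  reflectance_pre, reflectance_post``
- fixed network: ``site_id, week, weekly_mean, annual_mean, pollutant``
- surveys: ``child_id, school_id, source, verbal, numeric``
- covariates / meteorology: one row per school / week.

Ground truth is written to a separate file that no pipeline stage reads.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annoyance import SurveyResponse, responses_from_frame
from .pm_calibration import FilterSample
from .series import MinuteSeries
from .synthetic import GroundTruth, StudyBundle
from .temporal import FixedSiteNetwork


def write_minute_series(series_list: list[MinuteSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(path, index=False)


def read_minute_series(path: str | Path) -> dict[str, MinuteSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return {
        str(site): MinuteSeries.from_frame(g)
        for site, g in df.groupby("site_id", sort=True)
    }


def read_filter_log(path: str | Path) -> list[FilterSample]:
    df = pd.read_csv(path)
    samples = []
    for r in df.itertuples():
        samples.append(
            FilterSample(
                school_id=str(r.school_id),
                pre_mass=float(r.pre_mass_ug),
                post_mass=float(r.post_mass_ug),
                mean_flow=float(r.mean_flow_lpm),
                runtime=float(r.runtime_min),
                season=str(r.season),
                filter_area=float(r.filter_area_m2) if hasattr(r, "filter_area_m2") else None,
                reflectance_pre=float(r.reflectance_pre) if hasattr(r, "reflectance_pre") else None,
                reflectance_post=float(r.reflectance_post) if hasattr(r, "reflectance_post") else None,
            )
        )
    return samples


def read_network(path: str | Path, pollutant: str = "pm25") -> FixedSiteNetwork:
    return FixedSiteNetwork.from_frame(pd.read_csv(path), pollutant=pollutant)


def read_surveys(path: str | Path) -> list[SurveyResponse]:
    return responses_from_frame(pd.read_csv(path))


def write_study(bundle: StudyBundle, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write the synthetic study as the CSV set the pipeline reads.

    The ground-truth table goes to ``ground_truth.csv``, which only the
    evaluation (never the pipeline) may read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = bundle.to_frames()
    frames["network"].to_csv(out / "network.csv", index=False)
    frames["filters"].to_csv(out / "filters.csv", index=False)
    frames["covariates"].to_csv(out / "covariates.csv", index=False)
    frames["meteorology"].to_csv(out / "meteorology.csv", index=False)
    frames["surveys"].to_csv(out / "surveys.csv", index=False)
    frames["school_minutes"].to_csv(out / "school_minutes.csv", index=False)
    truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
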