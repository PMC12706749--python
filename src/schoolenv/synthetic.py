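"""Synthetic study generator with recorded ground truth.

Emulates a city-wide school exposure campaign: a fixed network of
ambient PM monitors running all year, schools measured one week each on
a rolling schedule, continuous PM monitors with a season-dependent
multiplicative bias alongside unbiased gravimetric filter samples,
minute-level schoolyard sound built from a quiet base plus Poisson loud
events, school covariates, weekly meteorology and child annoyance
surveys whose probability of being highly annoyed rises logistically
with school noise.

Every latent quantity (true annual means, the weekly temporal field,
instrument bias, true school-day noise levels, event minutes) is
recorded in a :class:`GroundTruth` object so that each downstream stage
can be tested by parameter recovery.  A single integer seed drives
deterministic per-component sub-streams: the same seed reproduces the
study bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .annoyance import NOISE_SOURCES, SurveyResponse
from .pm_calibration import HARMATTAN, NON_HARMATTAN, FilterSample
from .series import (
    BREAK_WINDOWS,
    SCHOOL_HOURS,
    ClockInterval,
    MinuteSeries,
    clock_mask,
    school_day_mask,
)
from .temporal import FixedSiteNetwork

MINUTES_PER_WEEK = 7 * 24 * 60


class ConfigError(ValueError):
    """A simulation-configuration field is invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design and ground-truth parameters of the synthetic city.

    Defaults mirror the field campaign being emulated: 90 schools
    measured five per week over 18 weeks, ten fixed ambient sites, a
    07:00–15:00 school day with two breaks, and continuous-monitor
    correction factors of 1.12 (Harmattan) / 0.83 (non-Harmattan).
    """

    n_schools: int = 90
    n_fixed_sites: int = 10
    weeks: int = 18
    minutes_per_week: int = MINUTES_PER_WEEK
    school_hours: ClockInterval = SCHOOL_HOURS
    break_windows: tuple[ClockInterval, ...] = BREAK_WINDOWS
    harmattan_weeks: frozenset[int] = frozenset({14, 15, 16, 17, 18})
    true_cf_harmattan: float = 1.12
    true_cf_nonharmattan: float = 0.83
    #: log-sd of the city-wide multiplicative weekly field.
    temporal_field_amplitude: float = 0.45
    #: Harmattan elevation of the log field, in units of the amplitude.
    harmattan_field_shift: float = 2.2
    school_annual_mean_range: tuple[float, float] = (11.0, 65.0)  # µg/m³
    school_annual_bc_range: tuple[float, float] = (1.7, 12.0)  # 10⁻⁵ m⁻¹
    noise_base_range: tuple[float, float] = (48.0, 62.0)  # dBA
    event_rate: float = 2.0  # loud events per hour
    event_gain: float = 15.0  # dBA added on event minutes
    sound_jitter_sd: float = 2.0  # dBA
    break_boost_dba: float = 0.7  # extra level during break windows
    annoy_intercept: float = -10.37  # logit scale at 0 dBA
    annoy_slope: float = 0.15  # logit per dBA of school noise
    n_children_per_school: int = 12
    #: lognormal sigmas for minute-level PM, school-week deviation from the
    #: city field, fixed-site week deviation, and continuous-monitor noise.
    pm_minute_sigma: float = 0.30
    school_week_sigma: float = 0.08
    site_week_sigma: float = 0.05
    monitor_noise_sigma: float = 0.10
    invalid_filter_rate: float = 0.10
    filter_area_m2: float = 8.0e-4
    filter_pre_mass_ug: float = 140000.0
    reflectance_pre: float = 0.95
    start_monday: str = "2022-06-06"
    seed: int = 0

    def validate(self) -> None:
        def fail(name: str, msg: str) -> None:
            raise ConfigError(f"{name}: {msg}")

        if self.n_schools < 1:
            fail("n_schools", "must be ≥ 1")
        if self.n_fixed_sites < 1:
            fail("n_fixed_sites", "must be ≥ 1")
        if self.weeks < 1:
            fail("weeks", "must be ≥ 1")
        if self.minutes_per_week != MINUTES_PER_WEEK:
            fail("minutes_per_week", f"must be {MINUTES_PER_WEEK} (7×24×60)")
        if not set(self.harmattan_weeks) <= set(range(1, self.weeks + 1)):
            fail("harmattan_weeks", f"must be a subset of 1..{self.weeks}")
        for name in ("true_cf_harmattan", "true_cf_nonharmattan"):
            if not getattr(self, name) > 0:
                fail(name, "must be positive")
        if self.temporal_field_amplitude < 0:
            fail("temporal_field_amplitude", "must be ≥ 0")
        for name in ("school_annual_mean_range", "school_annual_bc_range", "noise_base_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                fail(name, "low must be ≤ high")
        if self.event_rate < 0:
            fail("event_rate", "must be ≥ 0")
        if not 0 <= self.invalid_filter_rate <= 1:
            fail("invalid_filter_rate", "must be in [0, 1]")
        if self.n_children_per_school < 0:
            fail("n_children_per_school", "must be ≥ 0")

    def season_of(self, week: int) -> str:
        return HARMATTAN if week in self.harmattan_weeks else NON_HARMATTAN

    def true_cf(self, season: str) -> float:
        return self.true_cf_harmattan if season == HARMATTAN else self.true_cf_nonharmattan

    def week_index(self, week: int) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.start_monday) + pd.Timedelta(weeks=week - 1)
        return pd.date_range(start, periods=self.minutes_per_week, freq="min")


def config_to_file(config: SimConfig, path) -> None:
    """Write a config as a flat key = value text file."""
    lines = []
    for name, value in asdict(config).items():
        if isinstance(value, frozenset):
            value = ",".join(str(v) for v in sorted(value))
        elif isinstance(value, tuple):
            value = ";".join(
                "-".join(map(str, v)) if isinstance(v, tuple) else str(v) for v in value
            )
        lines.append(f"{name} = {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def config_from_file(path) -> SimConfig:
    """Read a flat key = value config file written by :func:`config_to_file`."""
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()

    kwargs: dict = {}
    ints = {
        "n_schools", "n_fixed_sites", "weeks", "minutes_per_week",
        "n_children_per_school", "seed",
    }
    floats = {
        "true_cf_harmattan", "true_cf_nonharmattan", "temporal_field_amplitude",
        "harmattan_field_shift", "event_rate", "event_gain", "sound_jitter_sd",
        "break_boost_dba", "annoy_intercept", "annoy_slope", "pm_minute_sigma",
        "school_week_sigma", "site_week_sigma", "monitor_noise_sigma",
        "invalid_filter_rate", "filter_area_m2", "filter_pre_mass_ug",
        "reflectance_pre",
    }
    pairs = {"school_annual_mean_range", "school_annual_bc_range", "noise_base_range"}
    for key, value in raw.items():
        if key in ints:
            kwargs[key] = int(value)
        elif key in floats:
            kwargs[key] = float(value)
        elif key in pairs:
            lo, hi = value.split(";")
            kwargs[key] = (float(lo), float(hi))
        elif key == "harmattan_weeks":
            kwargs[key] = frozenset(int(v) for v in value.split(",") if v)
        elif key == "school_hours":
            lo, hi = value.split(";")
            kwargs[key] = (lo, hi)
        elif key == "break_windows":
            kwargs[key] = tuple(tuple(w.split("-")) for w in value.split(";"))
        elif key == "start_monday":
            kwargs[key] = value
        else:
            raise ConfigError(f"{key}: unknown configuration field")
    return SimConfig(**kwargs)


@dataclass
class GroundTruth:
    """Latent parameters the pipeline should recover."""

    school_true_annual_pm: dict[str, float]
    school_true_annual_bc: dict[str, float]
    weekly_field: dict[int, float]
    school_true_Lday: dict[str, float]
    instrument_cf_by_season: dict[str, float]
    school_week: dict[str, int] = field(default_factory=dict)
    school_week_true_pm: dict[str, float] = field(default_factory=dict)
    school_week_true_bc: dict[str, float] = field(default_factory=dict)
    school_sound_base: dict[str, float] = field(default_factory=dict)
    sound_event_minutes: dict[str, np.ndarray] = field(default_factory=dict)
    annoy_p_ha: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for school in sorted(self.school_true_annual_pm):
            rows.append(
                {
                    "school_id": school,
                    "week": self.school_week.get(school),
                    "true_annual_pm25": self.school_true_annual_pm[school],
                    "true_annual_bc": self.school_true_annual_bc.get(school),
                    "week_true_pm25": self.school_week_true_pm.get(school),
                    "week_true_bc": self.school_week_true_bc.get(school),
                    "true_l_day_school": self.school_true_Lday.get(school),
                    "sound_base_dba": self.school_sound_base.get(school),
                    "p_highly_annoyed_road": self.annoy_p_ha.get(school),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SchoolDeployment:
    """One school's measurement week."""

    school_id: str
    week: int
    season: str
    continuous_pm: MinuteSeries  # biased monitor readings
    sound: MinuteSeries
    filter_sample: FilterSample


@dataclass
class StudyBundle:
    """Everything the pipeline consumes, for the whole synthetic study."""

    config: SimConfig
    fixed_pm_network: FixedSiteNetwork
    fixed_bc_network: FixedSiteNetwork
    fixed_site_series: dict[str, MinuteSeries]
    deployments: dict[str, SchoolDeployment]
    covariates: pd.DataFrame
    meteorology: pd.DataFrame
    surveys: list[SurveyResponse]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Tabular view of the bundle (used for CSV export and equality checks)."""
        net_rows = []
        for net in (self.fixed_pm_network, self.fixed_bc_network):
            for (site, week), v in sorted(net.weekly_means.items()):
                net_rows.append(
                    {
                        "site_id": site,
                        "week": week,
                        "weekly_mean": v,
                        "annual_mean": net.annual_means[site],
                        "pollutant": net.pollutant,
                    }
                )
        filt_rows = []
        for dep in self.deployments.values():
            s = dep.filter_sample
            filt_rows.append(
                {
                    "school_id": s.school_id,
                    "week": dep.week,
                    "pre_mass_ug": s.pre_mass,
                    "post_mass_ug": s.post_mass,
                    "mean_flow_lpm": s.mean_flow,
                    "runtime_min": s.runtime,
                    "season": s.season,
                    "filter_area_m2": s.filter_area,
                    "reflectance_pre": s.reflectance_pre,
                    "reflectance_post": s.reflectance_post,
                }
            )
        survey_rows = [
            {
                "child_id": r.child_id,
                "school_id": r.school_id,
                "source": r.source,
                "verbal": r.verbal,
                "numeric": r.numeric,
            }
            for r in self.surveys
        ]
        minutes = pd.concat(
            [d.continuous_pm.to_frame() for d in self.deployments.values()]
            + [d.sound.to_frame() for d in self.deployments.values()],
            ignore_index=True,
        )
        return {
            "network": pd.DataFrame(net_rows),
            "filters": pd.DataFrame(filt_rows).sort_values("school_id").reset_index(drop=True),
            "covariates": self.covariates.reset_index(drop=True),
            "meteorology": self.meteorology.reset_index(drop=True),
            "surveys": pd.DataFrame(survey_rows),
            "school_minutes": minutes,
        }


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic sub-stream generator keyed by (seed, stream ids)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def _meanone_lognormal(rng: np.random.Generator, sigma: float, size=None) -> np.ndarray:
    """Multiplicative noise with expectation exactly one."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def weekly_temporal_field(config: SimConfig) -> dict[int, float]:
    """City-wide multiplicative weekly field, normalized to mean one.

    Log-normal around one with Harmattan weeks elevated; amplitude zero
    gives a flat field of exact ones.
    """
    rng = _rng(config.seed, 1)
    weeks = np.arange(1, config.weeks + 1)
    z = rng.standard_normal(config.weeks)
    is_h = np.isin(weeks, list(config.harmattan_weeks)).astype(float)
    log_field = config.temporal_field_amplitude * (z + config.harmattan_field_shift * is_h)
    raw = np.exp(log_field)
    fieldv = raw / raw.mean()
    return {int(w): float(f) for w, f in zip(weeks, fieldv)}


def generate_sound_minutes(
    base_leq: float,
    event_rate: float,
    event_gain: float,
    n_minutes: int,
    seed: int | np.random.Generator,
    jitter_sd: float = 2.0,
    timestamps: pd.DatetimeIndex | None = None,
    site_id: str = "synthetic",
    break_boost: float = 0.0,
    break_windows: Sequence[ClockInterval] = (),
) -> tuple[MinuteSeries, np.ndarray]:
    """Minute sound levels: quiet base + Gaussian jitter + Poisson loud events.

    Each minute is independently an "event" with probability
    ``event_rate / 60``; event minutes are elevated by ``event_gain``
    dBA.  Returns the series and the boolean event mask (ground truth).
    """
    if n_minutes < 1:
        raise ValueError("n_minutes must be ≥ 1")
    if event_rate < 0:
        raise ValueError("event_rate must be ≥ 0")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), 2)
    if timestamps is None:
        timestamps = pd.date_range("2022-06-06", periods=n_minutes, freq="min")
    values = np.full(n_minutes, float(base_leq))
    if jitter_sd > 0:
        values = values + rng.normal(0.0, jitter_sd, n_minutes)
    events = rng.random(n_minutes) < event_rate / 60.0
    values = values + event_gain * events
    if break_boost != 0.0 and break_windows:
        boost_mask = clock_mask(timestamps, include=break_windows)
        values = values + break_boost * boost_mask
    series = MinuteSeries(site_id=site_id, timestamps=timestamps, values=values, kind="sound")
    return series, events


@dataclass(frozen=True)
class AnnoyParams:
    """Logistic model for the probability a child is highly annoyed."""

    intercept: float = -10.37
    slope: float = 0.15  # per dBA of school noise
    #: additive logit offsets per noise source (road traffic is the anchor;
    #: neighbor noise dominates, industrial/aircraft sources are minor).
    source_offsets: Mapping[str, float] = field(
        default_factory=lambda: {
            "road_traffic": 0.0,
            "aircraft": -0.9,
            "industry": -1.0,
            "business": -0.6,
            "neighbors": 2.2,
        }
    )
    n_children_per_school: int = 12


#: numeric-response distribution below the highly-annoyed range (0–7)
_LOW_NUMERIC_P = np.array([0.30, 0.20, 0.13, 0.10, 0.08, 0.07, 0.06, 0.06])


def verbal_from_numeric(numeric: int) -> int:
    """Fixed cut-points 0–1 / 2–4 / 5–6 / 7 / 8–10 → verbal categories 1–5."""
    if numeric <= 1:
        return 1
    if numeric <= 4:
        return 2
    if numeric <= 6:
        return 3
    if numeric == 7:
        return 4
    return 5


def generate_survey(
    school_noise: Mapping[str, float],
    params: AnnoyParams,
    seed: int | np.random.Generator,
) -> list[SurveyResponse]:
    """Child × source annoyance responses driven by school noise level.

    P(numeric ≥ 8) follows a logistic curve in the school's day-time
    noise level; the verbal answer is derived from the numeric one
    through fixed cut-points, so all three highly-annoyed metrics are
    coherent by construction.
    """
    if not (math.isfinite(params.intercept) and math.isfinite(params.slope)):
        raise ValueError("logit parameters must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), 3)
    responses: list[SurveyResponse] = []
    for school in sorted(school_noise):
        level = school_noise[school]
        for c in range(params.n_children_per_school):
            child_id = f"{school}-C{c + 1:02d}"
            for source in NOISE_SOURCES:
                offset = params.source_offsets.get(source, 0.0)
                p_ha = float(expit(params.intercept + offset + params.slope * level))
                if rng.random() < p_ha:
                    numeric = int(rng.choice([8, 9, 10], p=[0.5, 0.3, 0.2]))
                else:
                    numeric = int(rng.choice(np.arange(8), p=_LOW_NUMERIC_P))
                responses.append(
                    SurveyResponse(
                        child_id=child_id,
                        school_id=school,
                        source=source,
                        verbal=verbal_from_numeric(numeric),
                        numeric=numeric,
                    )
                )
    return responses


def _draw_covariates(rng: np.random.Generator, school_ids: Sequence[str]) -> pd.DataFrame:
    """School covariates with realistic marginals for an African metropolis.

    NDVI spans the observed 0–0.5 range, most schools lie within a few
    hundred metres of a major road, public schools dominate (74%), and
    districts follow the urban-core-heavy sampling of the design.
    """
    n = len(school_ids)
    return pd.DataFrame(
        {
            "school_id": list(school_ids),
            "ndvi": 0.5 * rng.beta(2.0, 3.0, n),
            "dist_major_road": rng.lognormal(math.log(300), 0.9, n),
            "dist_secondary_road": rng.lognormal(math.log(120), 0.8, n),
            "ses_index": rng.normal(7.5, 0.6, n),
            "surface": rng.choice(["paved", "unpaved"], n, p=[0.5, 0.5]),
            "school_type": rng.choice(["public", "private"], n, p=[0.74, 0.26]),
            "district": rng.choice(["AMA", "TMA", "other"], n, p=[0.34, 0.22, 0.44]),
            "commercial": rng.choice(["none", "market", "other"], n, p=[0.52, 0.18, 0.30]),
        }
    )


def _weekly_meteorology(config: SimConfig) -> pd.DataFrame:
    """Weekly mean temperature (°C), relative humidity (%) and rainfall (mm).

    Harmattan weeks are hotter, much drier and essentially rain-free."""
    rng = _rng(config.seed, 4)
    rows = []
    for week in range(1, config.weeks + 1):
        is_h = week in config.harmattan_weeks
        temp = 27.0 + 2.0 * is_h + rng.normal(0, 1.2)
        rh = float(np.clip(75.0 - 25.0 * is_h + rng.normal(0, 5.0), 20.0, 95.0))
        rain = 0.0 if is_h else float(rng.gamma(1.2, 5.0))
        rows.append({"week": week, "temperature": temp, "rh": rh, "rain": rain})
    return pd.DataFrame(rows)


def generate_study(config: SimConfig) -> tuple[StudyBundle, GroundTruth]:
    """Generate the full synthetic study and its ground truth.

    Identical configs (including the seed) yield bit-identical bundles.
    """
    config.validate()
    fieldv = weekly_temporal_field(config)
    weeks = range(1, config.weeks + 1)

    # ---- fixed ambient network ----------------------------------------
    pm_weekly: dict[tuple[str, int], float] = {}
    bc_weekly: dict[tuple[str, int], float] = {}
    site_series: dict[str, MinuteSeries] = {}
    for i in range(config.n_fixed_sites):
        site = f"FS{i + 1:02d}"
        rng = _rng(config.seed, 10, i)
        lo, hi = config.school_annual_mean_range
        annual_pm = rng.uniform(lo, hi)
        blo, bhi = config.school_annual_bc_range
        annual_bc = rng.uniform(blo, bhi)
        frames = []
        for week in weeks:
            week_true = annual_pm * fieldv[week] * _meanone_lognormal(rng, config.site_week_sigma)
            idx = config.week_index(week)
            minutes = week_true * _meanone_lognormal(rng, config.pm_minute_sigma, len(idx))
            pm_weekly[(site, week)] = float(minutes.mean())
            bc_weekly[(site, week)] = float(
                annual_bc * fieldv[week] * _meanone_lognormal(rng, config.site_week_sigma)
            )
            frames.append(pd.DataFrame({"timestamp": idx, "value": minutes}))
        all_minutes = pd.concat(frames, ignore_index=True)
        site_series[site] = MinuteSeries(
            site_id=site,
            timestamps=pd.DatetimeIndex(all_minutes["timestamp"]),
            values=all_minutes["value"].to_numpy(),
            kind="pm",
        )
    pm_network = FixedSiteNetwork(weekly_means=pm_weekly, pollutant="pm25")
    bc_network = FixedSiteNetwork(weekly_means=bc_weekly, pollutant="bc")

    # ---- school deployments --------------------------------------------
    truth = GroundTruth(
        school_true_annual_pm={},
        school_true_annual_bc={},
        weekly_field=fieldv,
        school_true_Lday={},
        instrument_cf_by_season={
            HARMATTAN: config.true_cf_harmattan,
            NON_HARMATTAN: config.true_cf_nonharmattan,
        },
    )
    deployments: dict[str, SchoolDeployment] = {}
    school_ids = [f"S{i + 1:03d}" for i in range(config.n_schools)]
    for i, school in enumerate(school_ids):
        week = 1 + i * config.weeks // config.n_schools
        season = config.season_of(week)
        cf = config.true_cf(season)
        rng = _rng(config.seed, 20, i)
        idx = config.week_index(week)

        lo, hi = config.school_annual_mean_range
        annual_pm = rng.uniform(lo, hi)
        week_dev = _meanone_lognormal(rng, config.school_week_sigma)
        week_true_mean = annual_pm * fieldv[week] * week_dev
        true_minutes = week_true_mean * _meanone_lognormal(rng, config.pm_minute_sigma, len(idx))
        # biased monitor: divide by the true CF so that correction recovers truth
        observed = (true_minutes / cf) * _meanone_lognormal(
            rng, config.monitor_noise_sigma, len(idx)
        )
        continuous = MinuteSeries(site_id=school, timestamps=idx, values=observed, kind="pm")

        blo, bhi = config.school_annual_bc_range
        annual_bc = rng.uniform(blo, bhi)
        week_bc = annual_bc * fieldv[week] * _meanone_lognormal(rng, config.school_week_sigma)

        # gravimetric filter: mass implied by the realized true series
        runtime = float(config.minutes_per_week)
        flow = 1.0
        if rng.random() < config.invalid_filter_rate:
            if rng.random() < 0.5:
                runtime = 0.60 * config.minutes_per_week
            else:
                flow = 1.15
        volume = flow * runtime / 1000.0
        operating = slice(0, int(round(runtime)))
        conc = float(true_minutes[operating].mean())
        r_pre = config.reflectance_pre
        r_post = r_pre * math.exp(-2.0 * volume * (week_bc * 1e-5) / config.filter_area_m2)
        filter_sample = FilterSample(
            school_id=school,
            pre_mass=config.filter_pre_mass_ug,
            post_mass=config.filter_pre_mass_ug + conc * volume,
            mean_flow=flow,
            runtime=runtime,
            season=season,
            filter_area=config.filter_area_m2,
            reflectance_pre=r_pre,
            reflectance_post=r_post,
        )

        nlo, nhi = config.noise_base_range
        base = rng.uniform(nlo, nhi)
        sound, events = generate_sound_minutes(
            base_leq=base,
            event_rate=config.event_rate,
            event_gain=config.event_gain,
            n_minutes=len(idx),
            seed=rng,
            jitter_sd=config.sound_jitter_sd,
            timestamps=idx,
            site_id=school,
            break_boost=config.break_boost_dba,
            break_windows=config.break_windows,
        )
        day_mask = school_day_mask(idx)
        true_lday = float(
            10.0 * np.log10(np.mean(10.0 ** (sound.values[day_mask] / 10.0)))
        )

        truth.school_true_annual_pm[school] = float(annual_pm)
        truth.school_true_annual_bc[school] = float(annual_bc)
        truth.school_week[school] = week
        truth.school_week_true_pm[school] = float(week_true_mean)
        truth.school_week_true_bc[school] = float(week_bc)
        truth.school_true_Lday[school] = true_lday
        truth.school_sound_base[school] = float(base)
        truth.sound_event_minutes[school] = events
        deployments[school] = SchoolDeployment(
            school_id=school,
            week=week,
            season=season,
            continuous_pm=continuous,
            sound=sound,
            filter_sample=filter_sample,
        )

    # ---- covariates, meteorology, surveys ------------------------------
    cov = _draw_covariates(_rng(config.seed, 5), school_ids)
    cov["season"] = [deployments[s].season for s in school_ids]
    cov["week"] = [deployments[s].week for s in school_ids]
    met = _weekly_meteorology(config)

    params = AnnoyParams(
        intercept=config.annoy_intercept,
        slope=config.annoy_slope,
        n_children_per_school=config.n_children_per_school,
    )
    surveys = generate_survey(truth.school_true_Lday, params, _rng(config.seed, 6))
    for school in school_ids:
        truth.annoy_p_ha[school] = float(
            expit(config.annoy_intercept + config.annoy_slope * truth.school_true_Lday[school])
        )

    bundle = StudyBundle(
        config=config,
        fixed_pm_network=pm_network,
        fixed_bc_network=bc_network,
        fixed_site_series=site_series,
        deployments=deployments,
        covariates=cov,
        meteorology=met,
        surveys=surveys,
    )
    return bundle, truth


def generate_determinant_table(
    n_schools: int = 90,
    effects: Mapping[str, float] | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
    constant_meteorology: bool = False,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Merged school table with known linear effects, for model testing.

    ``effects`` maps design-column names (e.g. ``commercial_market``,
    ``surface_paved``, ``ndvi``) to ln-scale coefficients; unlisted
    predictors are null.  Weekly temperature and rain enter the response
    nonlinearly (quadratic and square-root shapes) unless
    ``constant_meteorology`` is set, in which case all three meteorology
    columns are held fixed and the model reduces to a pure linear fit.
    Returns the table (with a positive ``pm25`` column whose log is the
    linear predictor plus noise) and the true effect map.
    """
    from .determinants import _design  # shared coding, avoids drift

    effects = dict(effects) if effects is not None else {"commercial_market": 0.3}
    rng = _rng(seed, 7)
    school_ids = [f"S{i + 1:03d}" for i in range(n_schools)]
    table = _draw_covariates(rng, school_ids)
    table["season"] = rng.choice([NON_HARMATTAN, HARMATTAN], n_schools, p=[0.72, 0.28])
    if constant_meteorology:
        table["temperature"] = 27.0
        table["rh"] = 75.0
        table["rain"] = 5.0
    else:
        table["temperature"] = rng.uniform(24.0, 32.0, n_schools)
        table["rh"] = rng.uniform(40.0, 90.0, n_schools)
        table["rain"] = rng.gamma(1.2, 5.0, n_schools)

    X = _design(table)
    eta = np.full(n_schools, 3.3)
    for name, beta in effects.items():
        if name not in X.columns:
            raise ValueError(f"unknown effect column {name!r}")
        eta = eta + beta * X[name].to_numpy()
    if not constant_meteorology:
        eta = eta + 0.015 * (table["temperature"].to_numpy() - 28.0) ** 2
        eta = eta + 0.08 * np.sqrt(table["rain"].to_numpy())
    eta = eta + rng.normal(0.0, noise_sd, n_schools)
    table["pm25"] = np.exp(eta)
    table["bc"] = np.exp(eta - 1.8)  # same structure on the BC scale
    table["leq_wk"] = 50.0 + 5.0 * (eta - eta.mean())
    return table, effects
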