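"""Temporal adjustment of one-week campaigns to annual-equivalent means.

Schools are measured one week each on a rolling schedule, so raw weekly
means confound place with time.  A fixed network of ambient monitors
provides, for every measurement week, a temporal adjustment factor
(TAF): the ratio of the network mean that week to the network annual
mean.  Dividing a school's weekly measurement by its week's TAF removes
the city-wide temporal multiplier and yields an annual-equivalent
concentration, making schools measured in different weeks comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import MinuteSeries, school_hours_mask


@dataclass(frozen=True)
class TAF:
    """Weekly temporal adjustment factor (week mean ÷ annual mean across sites)."""

    week: int
    value: float
    pollutant: str = "pm25"

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"TAF must be positive, got {self.value}")


@dataclass
class FixedSiteNetwork:
    """Weekly and annual mean concentrations at the fixed ambient sites.

    ``weekly_means`` maps ``(site_id, week)`` to a concentration;
    ``annual_means`` maps ``site_id`` to its annual mean.  If
    ``annual_means`` is not supplied it is derived as the mean of each
    site's available weekly means.
    """

    weekly_means: dict[tuple[str, int], float]
    annual_means: dict[str, float] = field(default_factory=dict)
    pollutant: str = "pm25"

    def __post_init__(self) -> None:
        if not self.annual_means:
            by_site: dict[str, list[float]] = {}
            for (site, _week), v in self.weekly_means.items():
                by_site.setdefault(site, []).append(v)
            self.annual_means = {s: float(np.mean(v)) for s, v in by_site.items()}
        bad = [k for k, v in {**self.weekly_means, **self.annual_means}.items() if not v > 0]
        if bad:
            raise ValueError(f"non-positive network concentrations at {bad[:3]}")

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.annual_means)

    @property
    def weeks(self) -> list[int]:
        return sorted({w for (_s, w) in self.weekly_means})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, pollutant: str = "pm25") -> "FixedSiteNetwork":
        df = frame[frame["pollutant"] == pollutant] if "pollutant" in frame else frame
        weekly = {
            (str(r.site_id), int(r.week)): float(r.weekly_mean) for r in df.itertuples()
        }
        annual: dict[str, float] = {}
        if "annual_mean" in df:
            annual = {str(r.site_id): float(r.annual_mean) for r in df.itertuples()}
        return cls(weekly_means=weekly, annual_means=annual, pollutant=pollutant)


@dataclass(frozen=True)
class AnnualEquivalent:
    """Annual-equivalent concentrations for one school."""

    school_id: str
    measurement_week: int
    pm25: float | None = None
    bc: float | None = None
    pm25_school_hours: float | None = None


def weekly_taf(network: FixedSiteNetwork, week: int) -> TAF:
    """TAF for one measurement week.

    Mean over sites of that week's mean, divided by the mean over the
    *same* sites of their annual means — sites missing the week drop out
    of both numerator and denominator, keeping the ratio paired.
    """
    sites = [s for s in network.site_ids if (s, week) in network.weekly_means]
    if not sites:
        raise ValueError(f"no fixed sites report week {week}")
    week_mean = float(np.mean([network.weekly_means[(s, week)] for s in sites]))
    annual_mean = float(np.mean([network.annual_means[s] for s in sites]))
    return TAF(week=week, value=week_mean / annual_mean, pollutant=network.pollutant)


def annualize(measured: float, taf: TAF) -> float:
    """Annual-equivalent concentration: measured weekly mean ÷ TAF.

    Division is the direction that undoes the city-wide weekly
    multiplier: a school tracking the city field with true annual mean m
    measures m·TAF in its week, and m·TAF / TAF = m.
    """
    if not measured > 0:
        raise ValueError(f"measured concentration must be positive, got {measured}")
    return measured / taf.value


def school_hours_mean(series: MinuteSeries, mask: np.ndarray | None = None) -> float:
    """Mean concentration over weekday school hours (07:00–15:00, Mon–Fri).

    The default mask selects exactly 2400 minutes (40 h) on a complete
    week.  Pass ``mask`` to override the minute selection.
    """
    if mask is None:
        mask = school_hours_mask(series.timestamps)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("series has no minutes within school hours")
    return float(np.mean(series.values[mask]))


def annualize_school(
    school_id: str,
    week: int,
    pm_network: FixedSiteNetwork,
    pm_week_mean: float,
    bc_network: FixedSiteNetwork | None = None,
    bc_week_value: float | None = None,
    pm_school_hours_mean: float | None = None,
) -> AnnualEquivalent:
    """Annual equivalents for one school's measurement week.

    The school-hours metric is adjusted by the same weekly PM TAF as the
    full-week mean, so both are reported on the annual-equivalent scale.
    """
    taf_pm = weekly_taf(pm_network, week)
    pm_annual = annualize(pm_week_mean, taf_pm)
    bc_annual = None
    if bc_network is not None and bc_week_value is not None:
        bc_annual = annualize(bc_week_value, weekly_taf(bc_network, week))
    sh_annual = None
    if pm_school_hours_mean is not None:
        sh_annual = annualize(pm_school_hours_mean, taf_pm)
    return AnnualEquivalent(
        school_id=school_id,
        measurement_week=week,
        pm25=pm_annual,
        bc=bc_annual,
        pm25_school_hours=sh_annual,
    )
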