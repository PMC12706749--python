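"""Gravimetric PM2.5 concentrations, QC rules and collocation correction factors.

Continuous optical monitors drift seasonally relative to the gravimetric
reference: during the dusty Harmattan season they under-read, outside it
they over-read.  Each collocation of a week-long filter sample with a
continuous monitor yields a correction factor (CF) defined as the ratio
that sets the continuous mean equal to the integrated filter
concentration.  Season-specific mean CFs are used to correct continuous
series at schools whose filter sample failed quality control.

The filter absorption coefficient (black-smoke proxy for black carbon) is
computed from pre/post filter reflectance with the standard formula
``a = (A / 2V) · ln(R_pre / R_post)``, reported in units of 10⁻⁵ m⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .series import PM, MinuteSeries

HARMATTAN = "Harmattan"
NON_HARMATTAN = "non-Harmattan"
SEASONS = (HARMATTAN, NON_HARMATTAN)

#: Nominal pump flow (l/min) and week length used by the QC rules.
NOMINAL_FLOW_LPM = 1.0
WEEK_MINUTES = 10080
RUNTIME_FRACTION_MIN = 0.75
FLOW_TOLERANCE = 0.10


class UndefinedVolumeError(ValueError):
    """Sampled air volume is zero or negative."""


@dataclass(frozen=True)
class FilterSample:
    """One week-long gravimetric filter deployment.

    Masses in µg, flows in l/min, runtime in minutes.  ``filter_area`` (m²)
    and the pre/post reflectances (0–1) are only needed for the absorption
    coefficient and may be left unset.
    """

    school_id: str
    pre_mass: float
    post_mass: float
    mean_flow: float
    runtime: float
    season: str
    nominal_flow: float = NOMINAL_FLOW_LPM
    filter_area: float | None = None
    reflectance_pre: float | None = None
    reflectance_post: float | None = None

    def volume_m3(self) -> float:
        """Sampled air volume in m³ (litres·minutes / 1000)."""
        return self.mean_flow * self.runtime / 1000.0


@dataclass(frozen=True)
class CorrectionFactor:
    """Multiplicative factor rescaling a continuous series to the gravimetric scale."""

    value: float
    season: str | None = None
    n_collocations: int = 1

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"correction factor must be positive, got {self.value}")


@dataclass(frozen=True)
class QCResult:
    valid: bool
    reasons: tuple[str, ...]


def gravimetric_concentration(sample: FilterSample) -> float:
    """Integrated PM2.5 concentration (µg/m³) from the filter mass gain.

    (post − pre) mass in µg divided by the sampled volume in m³.
    """
    volume = sample.volume_m3()
    if sample.runtime == 0 or sample.mean_flow <= 0 or volume <= 0:
        raise UndefinedVolumeError(
            f"sample {sample.school_id}: volume undefined "
            f"(flow={sample.mean_flow} l/min, runtime={sample.runtime} min)"
        )
    return (sample.post_mass - sample.pre_mass) / volume


def qc_filter_sample(sample: FilterSample) -> QCResult:
    """Classify a filter sample against the inclusion rules.

    Valid iff the pump ran for at least 75% of the week (≥7560 of 10080
    minutes) and the mean flow was within 10% of the nominal rate.  Both
    boundaries are inclusive.  ``reasons`` lists every failed rule.
    """
    reasons: list[str] = []
    if sample.runtime < RUNTIME_FRACTION_MIN * WEEK_MINUTES:
        reasons.append("runtime")
    if abs(sample.mean_flow - sample.nominal_flow) > FLOW_TOLERANCE * sample.nominal_flow:
        reasons.append("flow")
    return QCResult(valid=not reasons, reasons=tuple(reasons))


def collocation_cf(gravimetric: float, continuous: MinuteSeries, season: str | None = None) -> CorrectionFactor:
    """CF from one collocation: gravimetric concentration ÷ continuous mean.

    Applying the returned factor to the same series makes its mean equal
    the gravimetric value exactly (to floating tolerance).
    """
    if len(continuous) == 0:
        raise ValueError("continuous series is empty")
    cont_mean = continuous.mean()
    if cont_mean <= 0:
        raise ValueError(f"continuous mean must be positive, got {cont_mean}")
    if gravimetric <= 0:
        raise ValueError(f"gravimetric concentration must be positive, got {gravimetric}")
    return CorrectionFactor(value=gravimetric / cont_mean, season=season, n_collocations=1)


def seasonal_mean_cf(cfs: Iterable[CorrectionFactor]) -> dict[str, CorrectionFactor]:
    """Arithmetic mean CF per season over all collocations.

    Seasons with no collocations are absent from the result.
    """
    by_season: dict[str, list[float]] = {}
    for cf in cfs:
        if cf.season is None:
            raise ValueError("cannot pool a correction factor without a season label")
        by_season.setdefault(cf.season, []).append(cf.value)
    return {
        season: CorrectionFactor(
            value=float(np.mean(vals)), season=season, n_collocations=len(vals)
        )
        for season, vals in by_season.items()
    }


def apply_cf(series: MinuteSeries, cf: CorrectionFactor) -> MinuteSeries:
    """Multiply every minute value by the correction factor; timestamps unchanged."""
    if series.kind != PM:
        raise TypeError(f"correction factors apply to PM series, got kind={series.kind!r}")
    return series.with_values(series.values * cf.value)


def bc_absorption_coefficient(sample: FilterSample) -> float:
    """Filter absorption coefficient in units of 10⁻⁵ m⁻¹.

    ``a = (A / 2V) · ln(R_pre / R_post)`` with filter area A in m² and
    sampled volume V in m³.  A post reflectance above the pre reflectance
    (filter apparently brightened) yields a negative value with a warning.
    """
    if sample.filter_area is None or sample.reflectance_pre is None or sample.reflectance_post is None:
        raise ValueError("filter_area and both reflectances are required")
    if sample.reflectance_pre <= 0 or sample.reflectance_post <= 0:
        raise ValueError("reflectances must be in (0, 1]")
    volume = sample.volume_m3()
    if volume <= 0:
        raise UndefinedVolumeError(f"sample {sample.school_id}: sampled volume must be positive")
    if sample.reflectance_post > sample.reflectance_pre:
        warnings.warn(
            f"sample {sample.school_id}: post reflectance exceeds pre; negative absorbance",
            stacklevel=2,
        )
    a_per_m = (sample.filter_area / (2.0 * volume)) * math.log(
        sample.reflectance_pre / sample.reflectance_post
    )
    return a_per_m * 1e5
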