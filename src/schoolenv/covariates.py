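"""Spatial covariates and guideline classifications for schools.

Derives the categorical predictors used throughout the analysis —
NDVI vegetation class, road-proximity category, neighborhood SES median
split — plus exceedance classifications against the WHO annual PM2.5
air-quality guideline (with its interim targets) and the Ghana EPA
daytime noise standard for educational facilities (55 dBA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

BARE_SOIL = "bare_soil"
SPARSE_VEGETATION = "sparse_vegetation"
DENSE_VEGETATION = "dense_vegetation"

BELOW_MEDIAN = "below_median"
ABOVE_MEDIAN = "above_median"

WITHIN = "within"
BEYOND = "beyond"


@dataclass(frozen=True)
class SchoolCovariates:
    """Spatial and contextual covariates for one school."""

    school_id: str
    ndvi: float
    dist_major_road: float  # metres
    dist_secondary_road: float  # metres
    ses_index: float  # median log equivalized household consumption
    surface: str  # paved | unpaved
    school_type: str  # public | private
    district: str  # AMA | TMA | other
    commercial: str  # none | market | other
    season: str  # season of the measurement week

    def __post_init__(self) -> None:
        if self.dist_major_road < 0 or self.dist_secondary_road < 0:
            raise ValueError("road distances must be non-negative")
        if not -1.0 <= self.ndvi <= 1.0:
            raise ValueError(f"NDVI must be in [-1, 1], got {self.ndvi}")


@dataclass(frozen=True)
class GuidelineSet:
    """Health-based thresholds: WHO annual PM2.5 AQG + interim targets, Ghana EPA noise."""

    who_aqg: float = 5.0  # µg/m³ annual PM2.5
    who_interim: tuple[tuple[str, float], ...] = (
        ("IT-4", 10.0),
        ("IT-3", 15.0),
        ("IT-2", 25.0),
        ("IT-1", 35.0),
    )
    ghana_epa_school: float = 55.0  # dBA daytime at educational facilities

    def __post_init__(self) -> None:
        vals = [v for _n, v in self.who_interim]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("interim targets must be strictly increasing in concentration")


GUIDELINES = GuidelineSet()


def classify_ndvi(ndvi: float) -> str:
    """NDVI vegetation class: bare soil (≤0.1), sparse (0.2–0.5), dense (0.6–0.9).

    Values in the definitional gaps (0.1–0.2 and 0.5–0.6) are assigned
    to the class with the nearer boundary, with a warning.
    """
    if not -1.0 <= ndvi <= 1.0:
        raise ValueError(f"NDVI must be in [-1, 1], got {ndvi}")
    if ndvi <= 0.1:
        return BARE_SOIL
    if 0.2 <= ndvi <= 0.5:
        return SPARSE_VEGETATION
    if ndvi >= 0.6:
        return DENSE_VEGETATION
    if ndvi < 0.2:  # gap (0.1, 0.2)
        cls = BARE_SOIL if ndvi - 0.1 < 0.2 - ndvi else SPARSE_VEGETATION
    else:  # gap (0.5, 0.6)
        cls = SPARSE_VEGETATION if ndvi - 0.5 < 0.6 - ndvi else DENSE_VEGETATION
    warnings.warn(
        f"NDVI {ndvi:.3f} falls between class bounds; assigned {cls}", stacklevel=2
    )
    return cls


def ndvi_buffer_mean(
    grid: np.ndarray,
    cell_size: float,
    center: tuple[float, float],
    radius: float = 100.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Mean NDVI of grid cells whose centers fall within a circular buffer.

    ``grid`` is a 2-D array of NDVI values; cell (i, j) has its center at
    ``origin + ((j + 0.5)·cell, (i + 0.5)·cell)`` in (x, y) metres.
    """
    grid = np.asarray(grid, dtype=float)
    ny, nx = grid.shape
    xs = origin[0] + (np.arange(nx) + 0.5) * cell_size
    ys = origin[1] + (np.arange(ny) + 0.5) * cell_size
    xx, yy = np.meshgrid(xs, ys)
    inside = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
    if not inside.any():
        raise ValueError("buffer contains no grid cell centers")
    return float(grid[inside].mean())


def road_proximity_category(dist_major_road: float, cutoff: float = 500.0) -> str:
    """Whether a school lies within (≤ cutoff, inclusive) or beyond a major road."""
    if dist_major_road < 0:
        raise ValueError("distance must be non-negative")
    return WITHIN if dist_major_road <= cutoff else BEYOND


def ses_split(ses_values: Mapping[str, float]) -> dict[str, str]:
    """Median split of school neighborhood SES.

    Strictly below the median → ``below_median``; at or above →
    ``above_median`` (ties go above, so "below" is strictly below).
    """
    if not ses_values:
        raise ValueError("no SES values to split")
    median = float(np.percentile(list(ses_values.values()), 50))
    return {
        school: (BELOW_MEDIAN if v < median else ABOVE_MEDIAN)
        for school, v in ses_values.items()
    }


@dataclass(frozen=True)
class Exceedance:
    tier: str  # none | >IT-4 | >IT-3 | >IT-2 | >IT-1
    factor: float  # pm25 / AQG


def who_exceedance(pm25_annual: float, guidelines: GuidelineSet = GUIDELINES) -> Exceedance:
    """Fold exceedance of the WHO annual AQG and the highest interim target exceeded."""
    if not pm25_annual > 0:
        raise ValueError("PM2.5 must be positive")
    factor = pm25_annual / guidelines.who_aqg
    tier = "none"
    for name, threshold in guidelines.who_interim:
        if pm25_annual > threshold:
            tier = f">{name}"
    return Exceedance(tier=tier, factor=factor)


def ghana_epa_exceeds(l_day_school: float, guidelines: GuidelineSet = GUIDELINES) -> bool:
    """True iff the school-day noise level strictly exceeds the 55 dBA standard."""
    return l_day_school > guidelines.ghana_epa_school
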