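"""Noise-annoyance survey scoring and the exposure–response curve.

Children answer, per noise source, a 5-point verbal item (1 = not at
all … 5 = extremely) and an 11-point numeric item (0–10), following the
ISO/TS 15666 template.  Three "highly annoyed" (HA) percentages are
derived: HA_N (numeric ≥ 8), HA_V (verbal "very" or "extremely") and
HA_VW ("extremely" in full plus 0.4 × "very").  The exposure–response
curve pools respondents into 5 dB bins of measured school noise and fits
a quadratic of bin HA_N on bin midpoints by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

NOISE_SOURCES = ("road_traffic", "aircraft", "industry", "business", "neighbors")

#: Verbal weight applied to the "very" category in HA_VW.
VERY_WEIGHT = 0.4


@dataclass(frozen=True)
class SurveyResponse:
    """One child × noise-source annoyance record."""

    child_id: str
    school_id: str
    source: str
    verbal: int | None
    numeric: int | None

    def __post_init__(self) -> None:
        if self.verbal is not None and self.verbal not in range(1, 6):
            raise ValueError(f"verbal response must be 1–5, got {self.verbal}")
        if self.numeric is not None and self.numeric not in range(0, 11):
            raise ValueError(f"numeric response must be 0–10, got {self.numeric}")


@dataclass(frozen=True)
class HAResult:
    """Highly-annoyed percentages under the three definitions."""

    ha_n: float
    ha_v: float
    ha_vw: float
    n_respondents: int


def _for_source(responses: Iterable[SurveyResponse], source: str | None) -> list[SurveyResponse]:
    if source is None:
        return list(responses)
    return [r for r in responses if r.source == source]


def ha_numeric(responses: Iterable[SurveyResponse], source: str | None = None) -> float:
    """Percent of respondents with numeric annoyance 8, 9 or 10."""
    vals = [r.numeric for r in _for_source(responses, source) if r.numeric is not None]
    if not vals:
        raise ValueError(f"no numeric responses for source {source!r}")
    return 100.0 * sum(v >= 8 for v in vals) / len(vals)


def ha_verbal(responses: Iterable[SurveyResponse], source: str | None = None) -> float:
    """Percent of respondents in the top two verbal categories (very, extremely)."""
    vals = [r.verbal for r in _for_source(responses, source) if r.verbal is not None]
    if not vals:
        raise ValueError(f"no verbal responses for source {source!r}")
    return 100.0 * sum(v >= 4 for v in vals) / len(vals)


def ha_verbal_weighted(responses: Iterable[SurveyResponse], source: str | None = None) -> float:
    """Percent highly annoyed with "extremely" in full and "very" at weight 0.4."""
    vals = [r.verbal for r in _for_source(responses, source) if r.verbal is not None]
    if not vals:
        raise ValueError(f"no verbal responses for source {source!r}")
    score = sum(v == 5 for v in vals) + VERY_WEIGHT * sum(v == 4 for v in vals)
    return 100.0 * score / len(vals)


def ha_result(responses: Iterable[SurveyResponse], source: str | None = None) -> HAResult:
    rs = _for_source(responses, source)
    return HAResult(
        ha_n=ha_numeric(rs),
        ha_v=ha_verbal(rs),
        ha_vw=ha_verbal_weighted(rs),
        n_respondents=len(rs),
    )


def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """95% CI for a binomial proportion, in percent.

    Normal approximation for n ≥ 10; exact Clopper–Pearson for smaller
    bins where the approximation is unreliable.
    """
    p = k / n
    if n >= 10:
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(p * (1 - p) / n)
        lo, hi = max(0.0, p - half), min(1.0, p + half)
    else:
        alpha = 1 - level
        lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return 100.0 * lo, 100.0 * hi


@dataclass(frozen=True)
class ExposureResponse:
    """Binned exposure–response table and quadratic fit.

    ``bins`` has one row per non-empty 5 dB bin: bin_lo, bin_hi,
    midpoint, n, ha_percent, ci_low, ci_high.  ``coefficients`` are the
    OLS quadratic (c0, c1, c2) for HA% = c0 + c1·L + c2·L².
    """

    bins: pd.DataFrame
    coefficients: tuple[float, float, float]

    def predict(self, level: np.ndarray | float) -> np.ndarray | float:
        c0, c1, c2 = self.coefficients
        return c0 + c1 * np.asarray(level, dtype=float) + c2 * np.asarray(level, dtype=float) ** 2


def exposure_response(
    school_levels: Mapping[str, float],
    responses: Iterable[SurveyResponse],
    source: str = "road_traffic",
    bin_width: float = 5.0,
) -> ExposureResponse:
    """Respondent-pooled HA_N per 5 dB noise bin with a quadratic OLS fit.

    Bins are anchored at multiples of ``bin_width`` at or below the
    minimum school level, so every school falls in exactly one
    ``[lo, lo + width)`` bin.  Requires at least three non-empty bins
    (the quadratic has three parameters).
    """
    rs = [r for r in _for_source(responses, source) if r.numeric is not None]
    rs = [r for r in rs if r.school_id in school_levels]
    if not rs:
        raise ValueError(f"no responses with school levels for source {source!r}")
    levels = np.array([school_levels[r.school_id] for r in rs])
    highly = np.array([r.numeric >= 8 for r in rs], dtype=int)

    anchor = bin_width * np.floor(levels.min() / bin_width)
    bin_idx = np.floor((levels - anchor) / bin_width).astype(int)

    rows = []
    for b in sorted(set(bin_idx)):
        in_bin = bin_idx == b
        n = int(in_bin.sum())
        k = int(highly[in_bin].sum())
        lo = anchor + b * bin_width
        ci_lo, ci_hi = _binomial_ci(k, n)
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": lo + bin_width,
                "midpoint": lo + bin_width / 2,
                "n": n,
                "ha_percent": 100.0 * k / n,
                "ci_low": ci_lo,
                "ci_high": ci_hi,
            }
        )
    bins = pd.DataFrame(rows)
    if len(bins) < 3:
        raise ValueError(
            f"quadratic fit needs ≥3 non-empty bins, got {len(bins)}"
        )
    # unweighted OLS on bin aggregates
    coefs = np.polynomial.polynomial.polyfit(
        bins["midpoint"].to_numpy(), bins["ha_percent"].to_numpy(), deg=2
    )
    return ExposureResponse(bins=bins, coefficients=tuple(float(c) for c in coefs))


def responses_from_frame(frame: pd.DataFrame) -> list[SurveyResponse]:
    """Build survey responses from a table with columns child_id, school_id, source, verbal, numeric."""
    out = []
    for r in frame.itertuples():
        out.append(
            SurveyResponse(
                child_id=str(r.child_id),
                school_id=str(r.school_id),
                source=str(r.source),
                verbal=None if pd.isna(r.verbal) else int(r.verbal),
                numeric=None if pd.isna(r.numeric) else int(r.numeric),
            )
        )
    return out
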