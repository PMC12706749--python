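"""Equivalent continuous sound levels and the intermittency ratio.

All metrics work on minute-integrated A-weighted levels.  The equivalent
continuous level Leq is the energy mean, 10·log10 of the mean of
10^(L/10).  L_day(school) restricts to weekday school hours minus the
two break windows (children's own schoolyard noise); Leq_wk integrates
the whole week.  The intermittency ratio (IR) is the percentage of a
day's sound energy contributed by minutes exceeding that day's Leq plus
a fixed threshold (3 dBA by default) — high IR indicates event-driven
noise such as traffic pass-bys rather than a steady din.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .series import (
    BREAK_WINDOWS,
    SCHOOL_HOURS,
    WEEKDAYS,
    ClockInterval,
    MinuteSeries,
    clock_mask,
)

#: Default event threshold above the day Leq, in dBA.
IR_THRESHOLD_DBA = 3.0


@dataclass(frozen=True)
class NoiseMask:
    """Weekday/clock-interval selection with optional excluded windows."""

    weekday_set: frozenset[int] = WEEKDAYS
    include_intervals: tuple[ClockInterval, ...] = (SCHOOL_HOURS,)
    exclude_intervals: tuple[ClockInterval, ...] = BREAK_WINDOWS

    def minutes(self, index: pd.DatetimeIndex) -> np.ndarray:
        return clock_mask(
            index,
            include=self.include_intervals,
            weekdays=self.weekday_set,
            exclude=self.exclude_intervals,
        )

    def included_minutes(self, index: pd.DatetimeIndex) -> np.ndarray:
        """Mask without the exclusions (used to locate the excluded stratum)."""
        return clock_mask(index, include=self.include_intervals, weekdays=self.weekday_set)


SCHOOL_DAY_MASK = NoiseMask()


@dataclass(frozen=True)
class NoiseResult:
    l_day_school: float
    leq_wk: float
    ir: float
    minutes_used: dict[str, int] = field(default_factory=dict)


def leq(values: Sequence[float] | np.ndarray) -> float:
    """Equivalent continuous sound level of a set of minute levels (dBA)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("leq of an empty set of levels is undefined")
    return float(10.0 * np.log10(np.mean(10.0 ** (vals / 10.0))))


def l_day_school(series: MinuteSeries, mask: NoiseMask = SCHOOL_DAY_MASK) -> float:
    """Leq over weekday school hours excluding break windows.

    On a complete week the default mask selects 2100 minutes (35 h).
    """
    m = mask.minutes(series.timestamps)
    if not m.any():
        raise ValueError("series does not overlap the school-day mask")
    return leq(series.values[m])


def leq_wk(series: MinuteSeries) -> float:
    """Leq over the entire measurement series, no mask."""
    if len(series) == 0:
        raise ValueError("empty series")
    return leq(series.values)


def break_delta(series: MinuteSeries, mask: NoiseMask = SCHOOL_DAY_MASK) -> float:
    """Mean over school days of (break Leq − non-break school-hours Leq), dBA.

    Positive values mean breaks are louder than ordinary class hours.
    """
    idx = series.timestamps
    in_school = mask.included_minutes(idx)
    non_break = mask.minutes(idx)
    in_break = in_school & ~non_break
    if not in_break.any() or not non_break.any():
        raise ValueError("series must cover both break and non-break school minutes")
    days = idx.normalize()
    deltas = []
    for day in pd.unique(days[in_school]):
        on_day = np.asarray(days == day)
        b = in_break & on_day
        nb = non_break & on_day
        if b.any() and nb.any():
            deltas.append(leq(series.values[b]) - leq(series.values[nb]))
    if not deltas:
        raise ValueError("no day covers both break and non-break strata")
    return float(np.mean(deltas))


def intermittency_ratio(
    series: MinuteSeries,
    threshold_k: float = IR_THRESHOLD_DBA,
    window: NoiseMask | np.ndarray | None = None,
    aggregate: Literal["energy", "arithmetic"] = "energy",
) -> float:
    """Intermittency ratio in percent (0–100).

    Per local calendar day: the day's Leq sets the event cut-off at
    ``Leq_day + threshold_k``; minutes strictly above the cut-off are
    events; the day's IR is 100 × (event energy ÷ total energy).  Days
    are combined either weighted by their total energy (default) or as
    an arithmetic mean.
    """
    if threshold_k < 0:
        raise ValueError("threshold must be non-negative")
    idx = series.timestamps
    if window is None:
        m = np.ones(len(idx), dtype=bool)
    elif isinstance(window, NoiseMask):
        m = window.minutes(idx)
    else:
        m = np.asarray(window, dtype=bool)
    if not m.any():
        raise ValueError("window selects no minutes")
    sel_idx = idx[m]
    energy = 10.0 ** (series.values[m] / 10.0)
    days = sel_idx.normalize()

    day_ir = []
    day_energy = []
    for day in pd.unique(days):
        on_day = np.asarray(days == day)
        e = energy[on_day]
        leq_day = 10.0 * np.log10(e.mean())
        cutoff_energy = 10.0 ** ((leq_day + threshold_k) / 10.0)
        event = e > cutoff_energy
        total = e.sum()
        day_ir.append(100.0 * e[event].sum() / total)
        day_energy.append(total)

    if aggregate == "energy":
        w = np.asarray(day_energy)
        return float(np.average(day_ir, weights=w))
    if aggregate == "arithmetic":
        return float(np.mean(day_ir))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def noise_summary(
    series: MinuteSeries,
    mask: NoiseMask = SCHOOL_DAY_MASK,
    threshold_k: float = IR_THRESHOLD_DBA,
) -> NoiseResult:
    """All three site-level noise metrics with minute counts used by each."""
    idx = series.timestamps
    day_minutes = mask.minutes(idx)
    return NoiseResult(
        l_day_school=l_day_school(series, mask),
        leq_wk=leq_wk(series),
        ir=intermittency_ratio(series, threshold_k=threshold_k),
        minutes_used={
            "l_day_school": int(day_minutes.sum()),
            "leq_wk": len(series),
            "ir": len(series),
        },
    )
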