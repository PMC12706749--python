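"""Minute-resolution measurement series and clock masks.

A :class:`MinuteSeries` holds one instrument's week (or longer) of
minute-by-minute values at a single site: PM2.5 in µg/m³ or A-weighted
sound pressure level in dBA.  Clock masks select minutes by weekday and
local time-of-day; all intervals are half-open ``[start, end)`` and
minute-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PM = "pm"
SOUND = "sound"
_KINDS = {PM, SOUND}


@dataclass(frozen=True)
class MinuteSeries:
    """Timestamped minute-resolution measurements for one site/instrument.

    Parameters
    ----------
    site_id:
        Identifier of the school or fixed monitoring site.
    timestamps:
        Strictly increasing, minute-resolution local clock times.
    values:
        Measurements aligned with ``timestamps``; µg/m³ for ``kind="pm"``,
        dBA for ``kind="sound"``.
    kind:
        ``"pm"`` or ``"sound"``; a series never mixes units.
    """

    site_id: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if len(ts) != len(vals):
            raise ValueError("timestamps and values length mismatch")
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if ts.has_duplicates:
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray) -> "MinuteSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def select(self, mask: np.ndarray) -> "MinuteSeries":
        mask = np.asarray(mask, dtype=bool)
        return replace(self, timestamps=self.timestamps[mask], values=self.values[mask])

    def mean(self) -> float:
        return float(np.mean(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "timestamp": self.timestamps,
                "value": self.values,
                "kind": self.kind,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, site_id: str | None = None) -> "MinuteSeries":
        df = frame if site_id is None else frame[frame["site_id"] == site_id]
        if df.empty:
            raise ValueError(f"no rows for site {site_id!r}")
        kinds = df["kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"series mixes kinds: {sorted(kinds)}")
        df = df.sort_values("timestamp")
        return cls(
            site_id=str(df["site_id"].iloc[0]),
            timestamps=pd.DatetimeIndex(pd.to_datetime(df["timestamp"])),
            values=df["value"].to_numpy(dtype=float),
            kind=str(kinds[0]),
        )


def _parse_clock(t: str | tuple[int, int]) -> int:
    """Minute of day from 'HH:MM' or an (hour, minute) pair."""
    if isinstance(t, str):
        h, m = t.split(":")
        return int(h) * 60 + int(m)
    h, m = t
    return int(h) * 60 + int(m)


ClockInterval = tuple[str, str]

WEEKDAYS = frozenset({0, 1, 2, 3, 4})  # Monday..Friday
SCHOOL_HOURS: ClockInterval = ("07:00", "15:00")
BREAK_WINDOWS: tuple[ClockInterval, ...] = (("09:30", "10:00"), ("12:00", "12:30"))


def interval_mask(index: pd.DatetimeIndex, interval: ClockInterval) -> np.ndarray:
    """Boolean mask of minutes whose time-of-day lies in half-open ``[lo, hi)``."""
    lo, hi = (_parse_clock(t) for t in interval)
    mod = index.hour.to_numpy() * 60 + index.minute.to_numpy()
    return (mod >= lo) & (mod < hi)


def clock_mask(
    index: pd.DatetimeIndex,
    include: Iterable[ClockInterval] = (SCHOOL_HOURS,),
    weekdays: frozenset[int] | Iterable[int] = WEEKDAYS,
    exclude: Iterable[ClockInterval] = (),
) -> np.ndarray:
    """Select minutes in the included clock intervals on the given weekdays,
    minus any excluded intervals.

    A complete week with the default school-hours interval selects
    5 days × 8 h = 2400 minutes; additionally excluding the two standard
    break windows leaves 2100 minutes (35 h).
    """
    wd = index.weekday.to_numpy()
    day_ok = np.isin(wd, list(weekdays))
    inc = np.zeros(len(index), dtype=bool)
    for iv in include:
        inc |= interval_mask(index, iv)
    exc = np.zeros(len(index), dtype=bool)
    for iv in exclude:
        exc |= interval_mask(index, iv)
    return day_ok & inc & ~exc


def school_hours_mask(index: pd.DatetimeIndex) -> np.ndarray:
    """Weekday 07:00–15:00 mask (40 h on a complete week)."""
    return clock_mask(index, include=(SCHOOL_HOURS,))


def school_day_mask(index: pd.DatetimeIndex) -> np.ndarray:
    """Weekday school hours minus break windows (35 h on a complete week)."""
    return clock_mask(index, include=(SCHOOL_HOURS,), exclude=BREAK_WINDOWS)
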