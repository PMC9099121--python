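"""Exposure metrics derived from individual clearance and the actual
dosing history.

For linear kinetics the average exposure contributed by a day's dosing is
(total mg dosed that day) / CL/F, in mg·h/L = ug·h/mL.  All static metrics
are arithmetic means of this daily series over a window; windows are
1-based closed day ranges, and the between-scans window is the half-open
interval (previous scan day, last scan day].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .records import hour_to_day

__all__ = [
    "DailyExposureSeries",
    "daily_auc",
    "time_averaged_auc",
    "metric_between_last_two_scans",
    "metric_c1_days8_14",
    "metric_to_first_event",
]


@dataclass
class DailyExposureSeries:
    """Per-study-day AUC trajectory (ug·h/mL per day), day 1 to last day."""

    auc: np.ndarray  # index d-1 holds day d

    def __post_init__(self) -> None:
        self.auc = np.asarray(self.auc, dtype=float)
        if np.any(self.auc < 0):
            raise ValueError("daily AUC must be nonnegative")

    @property
    def study_day(self) -> np.ndarray:
        return np.arange(1, len(self.auc) + 1)

    @property
    def last_day(self) -> int:
        return len(self.auc)

    def value_on(self, day: int) -> float:
        if not 1 <= day <= self.last_day:
            raise ValueError(f"day {day} outside series (1..{self.last_day})")
        return float(self.auc[day - 1])


def daily_auc(doses, cl: float, last_day: int | None = None) -> DailyExposureSeries:
    """Daily AUC series from dose events and individual CL/F.

    Day ``d``'s AUC is (total mg dosed on day d) / cl; undosed days are 0.
    The series runs through ``last_day`` if given, else the last dosing day.
    """
    if cl <= 0:
        raise ValueError("clearance must be strictly positive")
    dosed = [(hour_to_day(d.time), d.amount) for d in doses if d.amount > 0]
    end = last_day if last_day is not None else (max(d for d, _ in dosed) if dosed else 1)
    series = np.zeros(int(end))
    for day, amt in dosed:
        if day <= end:
            series[day - 1] += amt / cl
    return DailyExposureSeries(series)


def time_averaged_auc(series: DailyExposureSeries, start_day: int, end_day: int) -> float:
    """Arithmetic mean of daily AUC over the closed window [start, end]."""
    if not (1 <= start_day <= end_day <= series.last_day):
        raise ValueError(
            f"window [{start_day}, {end_day}] invalid for series of "
            f"{series.last_day} days"
        )
    return float(np.mean(series.auc[start_day - 1 : end_day]))


def metric_between_last_two_scans(
    series: DailyExposureSeries, scan_days, event_or_censor_day: int
) -> float:
    """Time-averaged AUC between the last two disease-assessment scans at
    or before the event/censoring day: mean over (prev_scan, last_scan].

    With a single qualifying scan the window falls back to day 1 through
    that scan (flagged with a warning)."""
    scans = sorted(d for d in scan_days if d <= event_or_censor_day)
    if not scans:
        raise ValueError("no disease-assessment scan at or before the event day")
    if len(scans) == 1:
        warnings.warn(
            "single scan before event; falling back to window day 1 -> scan"
        )
        return time_averaged_auc(series, 1, min(scans[0], series.last_day))
    prev, last = scans[-2], scans[-1]
    last = min(last, series.last_day)
    return time_averaged_auc(series, prev + 1, last)


def metric_c1_days8_14(series: DailyExposureSeries) -> float:
    """Time-averaged AUC over cycle-one days 8-14 (the week following the
    escalation from 90 to 180 mg).  If treatment stopped before day 14 the
    mean runs over the available days (flagged)."""
    if series.last_day < 8:
        raise ValueError("series does not cover day 8")
    end = min(14, series.last_day)
    if end < 14:
        warnings.warn("treatment stopped before day 14; partial window used")
    return time_averaged_auc(series, 8, end)


def metric_to_first_event(
    series: DailyExposureSeries,
    event_day: int | None,
    end_of_treatment_day: int,
) -> float:
    """Time-averaged AUC from day 1 to the first event, or to the end of
    treatment when no event occurred."""
    if end_of_treatment_day < 1:
        raise ValueError("end of treatment must be at or after day 1")
    if event_day is not None and event_day < 1:
        raise ValueError("event day must be at or after day 1")
    end = event_day if event_day is not None else end_of_treatment_day
    return time_averaged_auc(series, 1, min(end, series.last_day))
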