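"""Per-subject data records: dosing events, concentration observations,
covariates and outcomes.

Time convention: hours since the first dose; study day ``d`` spans
``[24*(d-1), 24*d)`` hours, with day 1 the first dosing day.  Doses are mg,
concentrations ng/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def hour_to_day(time_h: float) -> int:
    """Study day containing hour ``time_h`` (day 1 starts at hour 0)."""
    return int(np.floor(time_h / 24.0)) + 1


@dataclass(frozen=True)
class DoseEvent:
    time: float  # h since first dose
    amount: float  # mg

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be nonnegative")
        if self.amount < 0:
            raise ValueError("dose amount must be nonnegative")


@dataclass(frozen=True)
class ConcObservation:
    time: float  # h since first dose
    value: float  # ng/mL
    blq: bool = False
    nominal: str = ""  # protocol time-point label, used for VPC binning

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be nonnegative")
        if not self.blq and self.value < 0:
            raise ValueError("quantifiable concentration must be nonnegative")


@dataclass
class SubjectRecord:
    """Everything known about one patient: covariates, dosing history,
    PK observations and outcome data."""

    subject_id: int
    covariates: dict = field(default_factory=dict)  # albumin, age, sex, ...
    doses: list = field(default_factory=list)  # list[DoseEvent], time-sorted
    observations: list = field(default_factory=list)  # list[ConcObservation]
    outcomes: dict = field(default_factory=dict)  # pfs_day, pfs_event, orr, ...

    def __post_init__(self) -> None:
        times = [d.time for d in self.doses]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"subject {self.subject_id}: dose events must be time-sorted"
            )

    @property
    def albumin(self) -> float:
        return float(self.covariates.get("albumin", 41.0))

    @property
    def last_dose_day(self) -> int:
        dosed = [d for d in self.doses if d.amount > 0]
        if not dosed:
            return 0
        return hour_to_day(max(d.time for d in dosed))

    def quantifiable(self) -> list:
        """Observations above the limit of quantification."""
        return [o for o in self.observations if not o.blq]
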