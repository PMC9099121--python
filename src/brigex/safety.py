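"""Exposure-safety analyses: adverse-event endpoint construction,
logistic exposure-AE models and the time-to-first-dose-reduction
Kaplan-Meier summary.

Endpoints are binary per subject: a qualifying AE record (configured term,
grade at or above threshold) with onset between the first dosing day and
30 days after the last dose.  The composite grade >= 3 endpoint is the
Boolean OR of its component endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .efficacy import ExposureLogitModel, KMStrata, LogisticFitResult, km_by_exposure_quartile

#: AE terms of interest with the grade thresholds analysed.
GRADE2_TERMS = (
    "alt_increase", "ast_increase", "amylase_increase", "hyperglycemia",
    "hypertension", "bradycardia", "rash", "pulmonary_ae",
)
GRADE3_TERMS = (
    "cpk_increase", "ast_increase", "alt_increase", "amylase_increase",
    "lipase_increase",
)
#: Components of the composite grade >= 3 endpoint.
COMPOSITE_G3_TERMS = (
    "cpk_increase", "ast_increase", "alt_increase", "amylase_increase",
    "lipase_increase", "hyperglycemia", "hypertension", "bradycardia",
    "rash", "pulmonary_ae",
)
KNOWN_TERMS = frozenset(GRADE2_TERMS) | frozenset(GRADE3_TERMS) | frozenset(COMPOSITE_G3_TERMS)

AE_WINDOW_AFTER_LAST_DOSE = 30  # days


@dataclass(frozen=True)
class AdverseEventRecord:
    subject: int
    ae_term: str
    grade: int
    onset_day: int

    def __post_init__(self) -> None:
        if not 1 <= self.grade <= 5:
            raise ValueError("AE grade must be 1..5")
        if self.ae_term not in KNOWN_TERMS:
            raise ValueError(f"unknown AE term {self.ae_term!r}")


def default_endpoint_definitions() -> list:
    """(name, term-or-None, grade threshold); term None marks the
    composite endpoint over COMPOSITE_G3_TERMS."""
    defs = [(f"{t}_g2", t, 2) for t in GRADE2_TERMS]
    defs += [(f"{t}_g3", t, 3) for t in GRADE3_TERMS]
    defs.append(("any_g3", None, 3))
    return defs


def build_endpoints(
    ae_records,
    last_dose_day_by_subject: dict,
    subjects=None,
    definitions=None,
) -> pd.DataFrame:
    """Binary safety endpoints with first-occurrence days.

    Returns a frame indexed by subject with columns ``<name>`` (0/1) and
    ``<name>_day`` (first qualifying onset day, NaN if never).  Records
    outside the first-dose -> last-dose + 30 days window are excluded.
    Construction is order-independent in the input records.
    """
    if definitions is None:
        definitions = default_endpoint_definitions()
    if subjects is None:
        subjects = sorted(last_dose_day_by_subject)
    for rec in ae_records:
        if rec.ae_term not in KNOWN_TERMS:
            raise ValueError(f"unknown AE term {rec.ae_term!r}")
    out = {}
    for name, term, thr in definitions:
        terms = COMPOSITE_G3_TERMS if term is None else (term,)
        flag = pd.Series(0, index=subjects, dtype=int)
        day = pd.Series(np.nan, index=subjects, dtype=float)
        for rec in ae_records:
            if rec.subject not in last_dose_day_by_subject:
                continue
            window_end = last_dose_day_by_subject[rec.subject] + AE_WINDOW_AFTER_LAST_DOSE
            if not 1 <= rec.onset_day <= window_end:
                continue
            if rec.ae_term in terms and rec.grade >= thr:
                flag[rec.subject] = 1
                prev = day[rec.subject]
                day[rec.subject] = rec.onset_day if np.isnan(prev) else min(prev, rec.onset_day)
        out[name] = flag
        out[f"{name}_day"] = day
    return pd.DataFrame(out)


def fit_ae_logistic(
    endpoint: pd.Series, exposure: pd.Series
) -> LogisticFitResult:
    """Logistic model of AE occurrence on a static exposure metric
    (time-averaged AUC to first occurrence / end of treatment, or the
    cycle-1 days 8-14 AUC)."""
    aligned = pd.concat([endpoint.rename("y"), exposure.rename("x")], axis=1).dropna()
    return ExposureLogitModel(aligned["x"], aligned["y"]).fit()


def time_to_dose_reduction_km(
    exposure, time_to_reduction, reduced, n_groups: int = 4
) -> KMStrata:
    """KM curves for time to first dose reduction, stratified by quartiles
    of time-averaged AUC to the first reduction (or end of treatment)."""
    return km_by_exposure_quartile(exposure, time_to_reduction, reduced, n_groups)
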