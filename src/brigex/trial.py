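"""Virtual-trial generator.

Emulates the design of a first-line ALK+ NSCLC trial arm: 123 subjects on
90 mg once daily for a 7-day lead-in then 180 mg once daily in 28-day
cycles, sparse PK sampling (cycle-1 day-1 predose; cycle-2 day-1 predose
and 1, 4, 7 h post-dose; one predose plus one 1-8 h post-dose sample on
day 1 of cycles three to five), disease-assessment scans every 8 weeks
through cycle 14 then every 12 weeks, random dose interruptions, a dose
ladder stepping 180 -> 120 -> 90 -> 60 mg at reduction events, and
progression / response / adverse-event outcomes generated from explicit
truth parameters so estimator recovery can be verified.

Every draw is taken from a per-subject, per-purpose ``numpy`` generator
seeded as ``(seed, subject_id, stream)``, so cohorts are byte-identical
under a fixed seed and stable under subsetting.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exposure import daily_auc, metric_c1_days8_14, metric_to_first_event
from .params import ETA_NAMES, PopPKParameters, apply_covariates_and_eta
from .pkmodel import simulate_concentrations, steady_state_daily_auc
from .records import ConcObservation, DoseEvent, SubjectRecord
from .safety import AdverseEventRecord

_STREAM_COVARIATES = 0
_STREAM_DOSING = 1
_STREAM_PK = 2
_STREAM_OUTCOMES = 3


def _rng(seed: int, subject_id: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, subject_id, stream])


@dataclass(frozen=True)
class TrialDesign:
    """Protocol-level settings of the virtual trial."""

    n_subjects: int = 123
    lead_in_dose: float = 90.0  # mg q.d.
    lead_in_days: int = 7
    maintenance_dose: float = 180.0  # mg q.d.
    cycle_days: int = 28
    scan_interval_early_days: int = 56  # every 8 weeks ...
    scan_switch_cycle: int = 14  # ... through cycle 14 ...
    scan_interval_late_days: int = 84  # ... then every 12 weeks
    reduction_ladder: tuple = (180.0, 120.0, 90.0, 60.0)
    dose_reduction_median_days: float = 730.0  # ~2 years to first reduction
    interruption_rate: float = 0.01  # per-day probability of a skipped dose
    max_follow_up_days: int = 1095

    def scan_days(self) -> list:
        switch = self.scan_switch_cycle * self.cycle_days
        days = list(range(self.scan_interval_early_days, switch + 1,
                          self.scan_interval_early_days))
        d = days[-1] if days else 0
        while d + self.scan_interval_late_days <= self.max_follow_up_days:
            d += self.scan_interval_late_days
            days.append(d)
        return days

    def pk_sampling(self, rng: np.random.Generator) -> list:
        """(time h, nominal label) pairs; window samples are drawn
        uniformly on 1-8 h post-dose."""
        samples = [(0.0, "C1D1-pre")]
        c2 = (2 - 1) * self.cycle_days * 24.0
        samples.append((c2, "C2D1-pre"))
        for off in (1.0, 4.0, 7.0):
            samples.append((c2 + off, f"C2D1+{off:g}h"))
        for cyc in (3, 4, 5):
            t0 = (cyc - 1) * self.cycle_days * 24.0
            samples.append((t0, f"C{cyc}D1-pre"))
            samples.append((t0 + rng.uniform(1.0, 8.0), f"C{cyc}D1-post"))
        return samples


#: Exposure-response truth used by the outcome generator.  Effect sizes
#: default to the reported first-line estimates: hazard ratio 1.03 per
#: ug·h/mL for the static exposure-PFS relation, odds ratios 1.13 (iORR,
#: anchored at probability 0.83 at the reference exposure), 0.97 (ORR),
#: 1.06 (grade >= 2 amylase) and 1.05 (grade >= 3 lipase) with marginal
#: incidences 19.5% and 17.9%; remaining AE endpoints are
#: exposure-independent at their observed incidences.
@dataclass(frozen=True)
class OutcomeTruth:
    auc_ref: float = 21.3  # ug·h/mL, reference (geometric-mean) exposure
    pfs_log_hr: float = float(np.log(1.03))  # per ug·h/mL of daily AUC
    pfs_median_days: float = 730.0
    pfs_weibull_shape: float = 1.0
    orr_or: float = 0.97
    orr_prob_ref: float = 0.74
    iorr_or: float = 1.13
    iorr_prob_ref: float = 0.83
    ae_truth: dict = field(default_factory=lambda: {
        "hypertension_g2": (1.0, 0.309),
        "cpk_increase_g3": (1.0, 0.260),
        "lipase_increase_g3": (1.05, 0.179),
        "rash_g2": (1.0, 0.122),
        "amylase_increase_g2": (1.06, 0.195),
        "amylase_increase_g3": (1.0, 0.081),
        "alt_increase_g2": (1.0, 0.146),
        "alt_increase_g3": (1.0, 0.049),
        "ast_increase_g2": (1.0, 0.081),
        "ast_increase_g3": (1.0, 0.041),
        "bradycardia_g2": (1.0, 0.016),
        "hyperglycemia_g2": (1.0, 0.016),
        "pulmonary_ae_g2": (1.0, 0.016),
    })


def _truncnorm(rng, loc, scale, lo, hi, size=None):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    return loc + scale * stats.norm.ppf(u)


def generate_covariates(subject_id: int, seed: int) -> dict:
    """Baseline covariates drawn from parametric approximations to the
    trial's summary statistics (medians/ranges for continuous covariates,
    stated proportions for categorical ones)."""
    rng = _rng(seed, subject_id, _STREAM_COVARIATES)
    sex = "male" if rng.random() < 0.512 else "female"
    weight = (_truncnorm(rng, 72.0, 12.0, 43.0, 111.0) if sex == "male"
              else _truncnorm(rng, 62.0, 10.0, 43.0, 111.0))
    race = rng.choice(["white", "asian", "other"], p=[0.553, 0.431, 0.016])
    ecog = int(rng.choice([0, 1, 2], p=[0.398, 0.561, 0.041]))
    return {
        "age": float(_truncnorm(rng, 57.0, 12.0, 27.0, 85.0)),
        "albumin": float(_truncnorm(rng, 41.0, 4.5, 24.0, 48.0)),
        "weight": float(weight),
        "sex": sex,
        "race": str(race),
        "ecog": ecog,
        "prior_chemo": int(rng.random() < 0.285),
        "brain_mets": int(rng.random() < 0.293),
        "smoker": int(rng.random() < 0.35),
        "alt": float(np.exp(_truncnorm(rng, np.log(20.0), 0.5, np.log(5.0), np.log(118.0)))),
        "ast": float(np.exp(_truncnorm(rng, np.log(20.0), 0.45, np.log(9.0), np.log(111.0)))),
        "bilirubin": float(np.exp(_truncnorm(rng, np.log(8.0), 0.4, np.log(3.0), np.log(34.0)))),
        "egfr": float(_truncnorm(rng, 92.0, 25.0, 40.0, 178.0)),
        "log_lesion_sum": float(_truncnorm(rng, 3.92, 0.7, 2.34, 5.4)),
    }


def generate_cohort(design: TrialDesign, pop: PopPKParameters, seed: int):
    """Subjects with covariates and true individual PK parameters.

    Returns (subjects, truth) where ``truth`` maps subject id to the true
    eta vector and derived individual parameters.
    """
    if design.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    chol = np.linalg.cholesky(pop.omega + 1e-12 * np.eye(len(ETA_NAMES)))
    subjects, truth = [], {}
    for sid in range(1, design.n_subjects + 1):
        cov = generate_covariates(sid, seed)
        rng = np.random.default_rng([seed, sid, _STREAM_COVARIATES, 1])
        eta = chol @ rng.standard_normal(len(ETA_NAMES))
        ind = apply_covariates_and_eta(pop, cov["albumin"], eta)
        subjects.append(SubjectRecord(subject_id=sid, covariates=cov))
        truth[sid] = {
            "eta": eta.tolist(),
            "cl": ind.cl, "v1": ind.v1, "v2": ind.v2,
            "n_transit": ind.n_transit, "mtt": ind.mtt,
            "auc_ss": steady_state_daily_auc(design.maintenance_dose, ind.cl),
        }
    return subjects, truth


def generate_dosing(subject_id: int, design: TrialDesign, seed: int):
    """Full-horizon dosing history (later truncated at end of treatment).

    Returns (dose_events, first_reduction_day or None).  Reduction times
    follow an exponential clock with the design's median; at each event
    the dose steps down the ladder.  Interrupted days emit no dose.
    """
    rng = _rng(seed, subject_id, _STREAM_DOSING)
    rate = (np.log(2.0) / design.dose_reduction_median_days
            if design.dose_reduction_median_days > 0 else 0.0)
    reduction_days = []
    if rate > 0:
        d = 0.0
        for _ in range(len(design.reduction_ladder) - 1):
            d += rng.exponential(1.0 / rate)
            if d > design.max_follow_up_days:
                break
            reduction_days.append(int(np.ceil(d)))
    ladder = list(design.reduction_ladder)
    doses = []
    level = 0
    for day in range(1, design.max_follow_up_days + 1):
        while reduction_days and day >= reduction_days[0]:
            reduction_days.pop(0)
            level = min(level + 1, len(ladder) - 1)
        if day <= design.lead_in_days:
            amount = design.lead_in_dose
        else:
            amount = ladder[level]
        if design.interruption_rate > 0 and rng.random() < design.interruption_rate:
            continue
        doses.append(DoseEvent(time=24.0 * (day - 1), amount=amount))
    first_red = None
    # recover first reduction day from the emitted schedule (robust to
    # interruptions): first day whose dose drops below the protocol dose
    for d in doses:
        day = int(d.time // 24) + 1
        protocol = design.lead_in_dose if day <= design.lead_in_days else design.maintenance_dose
        if d.amount < protocol:
            first_red = day
            break
    return doses, first_red


def generate_pk_observations(
    subject: SubjectRecord, ind, design: TrialDesign, pop: PopPKParameters,
    seed: int, end_day: int,
) -> list:
    """Sparse PK samples on the protocol schedule with combined
    proportional + additive residual noise; values below the limit of
    quantification are flagged BLQ."""
    rng = _rng(seed, subject.subject_id, _STREAM_PK)
    schedule = [(t, lab) for t, lab in design.pk_sampling(rng)
                if t < end_day * 24.0]
    if not schedule:
        return []
    times = np.array([t for t, _ in schedule])
    order = np.argsort(times)
    f = np.empty_like(times)
    f[order] = simulate_concentrations(ind, subject.doses, times[order])
    obs = []
    for (t, lab), fi in zip(schedule, f):
        y = fi * (1.0 + rng.standard_normal() * pop.sigma_prop)
        y += rng.standard_normal() * pop.sigma_add
        y = max(y, 0.0)
        obs.append(ConcObservation(time=t, value=y, blq=bool(y < pop.lloq),
                                   nominal=lab))
    return obs


def _anchored_intercept(slope: float, target_rate: float, metric: np.ndarray) -> float:
    """Intercept such that the cohort-average response probability equals
    the target marginal incidence."""
    def gap(b0):
        return np.mean(1.0 / (1.0 + np.exp(-(b0 + slope * metric)))) - target_rate
    return float(optimize.brentq(gap, -30.0, 30.0))


def _simulate_pfs(series_auc: np.ndarray, truth: OutcomeTruth, design: TrialDesign,
                  rng: np.random.Generator):
    """Day-by-day progression draw under a hazard modulated by the current
    daily AUC; returns (time, event)."""
    shape = truth.pfs_weibull_shape
    scale = truth.pfs_median_days / np.log(2.0) ** (1.0 / shape)
    beta = truth.pfs_log_hr
    max_d = design.max_follow_up_days
    for day in range(1, max_d + 1):
        # baseline cumulative hazard increment over the day
        h0 = ((day / scale) ** shape - ((day - 1) / scale) ** shape)
        auc_d = series_auc[day - 1] if day <= len(series_auc) else 0.0
        h = h0 * np.exp(beta * (auc_d - truth.auc_ref))
        if rng.random() < 1.0 - np.exp(-h):
            return float(day), 1
    return float(max_d), 0


@dataclass
class VirtualTrial:
    """Generated arm: subjects with full data plus the generating truth."""

    design: TrialDesign
    pop: PopPKParameters
    truth_params: OutcomeTruth
    seed: int
    subjects: list
    subject_truth: dict
    tte: pd.DataFrame  # subject, time, event (PFS)
    responses: pd.DataFrame  # subject, orr, iorr (iorr NaN without brain mets)
    ae_records: list
    dose_reduction: pd.DataFrame  # subject, time, reduced

    def truth_json(self) -> str:
        payload = {
            "seed": self.seed,
            "outcome_truth": {k: (v if not isinstance(v, dict) else v)
                              for k, v in asdict(self.truth_params).items()},
            "subjects": self.subject_truth,
        }
        return json.dumps(payload, sort_keys=True)

    @staticmethod
    def truth_from_json(s: str) -> dict:
        return json.loads(s)


def simulate_trial(
    design: TrialDesign | None = None,
    pop: PopPKParameters | None = None,
    truth: OutcomeTruth | None = None,
    seed: int = 0,
) -> VirtualTrial:
    """Generate a complete virtual trial arm.

    Pipeline per subject: covariates and true PK parameters, dosing
    history with interruptions and reductions, progression time under the
    exposure-modulated hazard (treatment and follow-up end at progression
    or administrative censoring), sparse PK sampling while on treatment,
    response and AE outcomes from the logistic truths.
    """
    design = design or TrialDesign()
    pop = pop or PopPKParameters.from_yaml()
    truth = truth or OutcomeTruth()
    subjects, subject_truth = generate_cohort(design, pop, seed)

    series_all, first_red = {}, {}
    for s in subjects:
        doses, red_day = generate_dosing(s.subject_id, design, seed)
        s.doses = doses
        cl = subject_truth[s.subject_id]["cl"]
        series_all[s.subject_id] = daily_auc(doses, cl,
                                             last_day=design.max_follow_up_days)
        first_red[s.subject_id] = red_day

    # progression / censoring
    tte_rows = []
    for s in subjects:
        rng = _rng(seed, s.subject_id, _STREAM_OUTCOMES)
        t, ev = _simulate_pfs(series_all[s.subject_id].auc, truth, design, rng)
        tte_rows.append({"subject": s.subject_id, "time": t, "event": ev})
        end_day = int(t)
        s.outcomes["pfs_day"] = t
        s.outcomes["pfs_event"] = ev
        s.outcomes["end_of_treatment_day"] = end_day
        # truncate dosing at end of treatment
        s.doses = [d for d in s.doses if d.time < end_day * 24.0]
        ind = apply_covariates_and_eta(
            pop, s.albumin, np.array(subject_truth[s.subject_id]["eta"])
        )
        s.observations = generate_pk_observations(s, ind, design, pop, seed, end_day)
    tte = pd.DataFrame(tte_rows)

    # response outcomes on the steady-state exposure truth
    auc_ss = np.array([subject_truth[s.subject_id]["auc_ss"] for s in subjects])
    scans = design.scan_days()
    resp_rows = []
    from scipy.special import logit

    b0_orr = (logit(truth.orr_prob_ref) - np.log(truth.orr_or) * truth.auc_ref
              if 0 < truth.orr_prob_ref < 1 else None)
    b0_iorr = (logit(truth.iorr_prob_ref) - np.log(truth.iorr_or) * truth.auc_ref
               if 0 < truth.iorr_prob_ref < 1 else None)
    for s, a in zip(subjects, auc_ss):
        rng = np.random.default_rng([seed, s.subject_id, _STREAM_OUTCOMES, 1])
        p_orr = 1.0 / (1.0 + np.exp(-(b0_orr + np.log(truth.orr_or) * a)))
        orr = int(rng.random() < p_orr)
        iorr = np.nan
        if s.covariates.get("brain_mets"):
            p_iorr = 1.0 / (1.0 + np.exp(-(b0_iorr + np.log(truth.iorr_or) * a)))
            iorr = int(rng.random() < p_iorr)
        # best-response assessment day: one of the first three scans
        resp_day = scans[int(rng.integers(0, 3))]
        resp_rows.append({"subject": s.subject_id, "orr": orr, "iorr": iorr,
                          "response_day": resp_day})
        s.outcomes["orr"] = orr
        s.outcomes["iorr"] = iorr
        s.outcomes["response_day"] = resp_day
    responses = pd.DataFrame(resp_rows)

    # adverse events on the cycle-1 week-2 exposure metric
    metric = np.array([
        metric_c1_days8_14(series_all[s.subject_id]) for s in subjects
    ])
    ae_records = []
    for name, (or_unit, incidence) in truth.ae_truth.items():
        slope = np.log(or_unit)
        b0 = _anchored_intercept(slope, incidence, metric)
        term, grade = name.rsplit("_g", 1)
        name_key = zlib.crc32(name.encode()) % (2**31)
        for s, m in zip(subjects, metric):
            rng = np.random.default_rng(
                [seed, s.subject_id, _STREAM_OUTCOMES, 2, name_key]
            )
            p = 1.0 / (1.0 + np.exp(-(b0 + slope * m)))
            if rng.random() < p:
                eot = int(s.outcomes["end_of_treatment_day"])
                onset = int(rng.integers(1, max(eot, 1) + 1))
                ae_records.append(AdverseEventRecord(
                    subject=s.subject_id, ae_term=term, grade=int(grade),
                    onset_day=onset,
                ))

    # dose-reduction table (censored at end of treatment)
    red_rows = []
    for s in subjects:
        eot = s.outcomes["end_of_treatment_day"]
        rd = first_red[s.subject_id]
        if rd is not None and rd <= eot:
            red_rows.append({"subject": s.subject_id, "time": float(rd),
                             "reduced": 1})
        else:
            red_rows.append({"subject": s.subject_id, "time": float(eot),
                             "reduced": 0})
        s.outcomes["first_reduction_day"] = rd if (rd and rd <= eot) else None
    dose_reduction = pd.DataFrame(red_rows)

    return VirtualTrial(
        design=design, pop=pop, truth_params=truth, seed=seed,
        subjects=subjects, subject_truth=subject_truth, tte=tte,
        responses=responses, ae_records=ae_records,
        dose_reduction=dose_reduction,
    )


def exposure_series(trial: VirtualTrial, sid: int):
    """Daily AUC series over the subject's treatment period, from the
    true clearance and the truncated dosing history."""
    s = next(x for x in trial.subjects if x.subject_id == sid)
    cl = trial.subject_truth[sid]["cl"]
    last = max(int(s.outcomes["end_of_treatment_day"]), 1)
    return daily_auc(s.doses, cl, last_day=last)


def static_exposure_metrics(trial: VirtualTrial) -> pd.DataFrame:
    """Per-subject static exposure metrics from true clearances: the
    steady-state AUC, time-averaged AUC to progression / end of treatment,
    and the cycle-1 days 8-14 AUC."""
    rows = []
    for s in trial.subjects:
        sid = s.subject_id
        series = exposure_series(trial, sid)
        event_day = (int(s.outcomes["pfs_day"]) if s.outcomes["pfs_event"]
                     else None)
        rows.append({
            "subject": sid,
            "auc_ss": trial.subject_truth[sid]["auc_ss"],
            "auc_to_event": metric_to_first_event(
                series, event_day, int(s.outcomes["end_of_treatment_day"])),
            "auc_c1_d8_14": metric_c1_days8_14(series)
            if series.last_day >= 8 else np.nan,
        })
    return pd.DataFrame(rows).set_index("subject")
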