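"""Operating-characteristic simulations for the exposure-response
estimators: parameter recovery at the trial's sample sizes and effect
sizes, confidence-interval coverage, and the bias mechanism that makes
static exposure metrics misleading when dose reductions accumulate in
long survivors.

Exposure distributions are lognormal, parameterised by a geometric mean
and 5th/95th percentiles so simulated cohorts match the observed
steady-state AUC spread (geometric mean 21.3, 5th/95th 10.1/44.6
ug·h/mL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .efficacy import ExposureCoxModel, ExposureLogitModel, ExposureTimeVaryingCoxModel
from .exposure import DailyExposureSeries

AUC_GM = 21.3
AUC_P5 = 10.1
AUC_P95 = 44.6


def lognormal_auc_sigma(gm: float = AUC_GM, p5: float = AUC_P5,
                        p95: float = AUC_P95) -> float:
    """Log-scale SD matching the stated 5th/95th percentiles (averaged
    over the two tails)."""
    z95 = 1.6448536269514722
    return 0.5 * (np.log(p95 / gm) + np.log(gm / p5)) / z95


def draw_auc(rng: np.random.Generator, n: int, gm: float = AUC_GM,
             sigma: float | None = None) -> np.ndarray:
    if sigma is None:
        sigma = lognormal_auc_sigma(gm=gm)
    return np.exp(rng.normal(np.log(gm), sigma, n))


def incidence_anchored_intercept(slope: float, incidence: float,
                                 gm: float = AUC_GM,
                                 sigma: float | None = None) -> float:
    """Intercept such that the marginal response probability over the
    lognormal exposure distribution equals the target incidence
    (Gauss-Hermite integration plus root finding)."""
    if sigma is None:
        sigma = lognormal_auc_sigma(gm=gm)
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    auc = np.exp(np.log(gm) + sigma * nodes)
    w = weights / weights.sum()

    def gap(b0):
        return float(w @ expit(b0 + slope * auc)) - incidence

    return float(optimize.brentq(gap, -30.0, 30.0))


@dataclass
class RecoveryResult:
    """Replicate-level estimates from a recovery simulation."""

    estimates: pd.DataFrame  # columns: estimate, ci_low, ci_high
    true_value: float
    n_failed: int = 0

    @property
    def mean_estimate(self) -> float:
        return float(self.estimates["estimate"].mean())

    @property
    def coverage(self) -> float:
        hit = ((self.estimates["ci_low"] <= self.true_value)
               & (self.true_value <= self.estimates["ci_high"]))
        return float(hit.mean())

    @property
    def mc_se(self) -> float:
        return float(self.estimates["estimate"].std(ddof=1)
                     / np.sqrt(len(self.estimates)))


def logistic_or_recovery(
    n: int,
    or_per_unit: float,
    anchor_prob: float | None = None,
    anchor_auc: float = AUC_GM,
    incidence: float | None = None,
    n_rep: int = 500,
    seed: int = 0,
) -> RecoveryResult:
    """Recovery of a logistic odds ratio per 1 ug·h/mL.

    The intercept is anchored either at a stated probability at
    ``anchor_auc`` (response-rate style) or at a marginal incidence over
    the exposure distribution (adverse-event style).  Replicates with a
    single response class are skipped and counted.
    """
    slope = np.log(or_per_unit)
    if incidence is not None:
        b0 = incidence_anchored_intercept(slope, incidence)
    elif anchor_prob is not None:
        b0 = logit(anchor_prob) - slope * anchor_auc
    else:
        raise ValueError("provide anchor_prob or incidence")
    rng = np.random.default_rng(seed)
    rows, failed = [], 0
    for _ in range(n_rep):
        auc = draw_auc(rng, n)
        y = (rng.random(n) < expit(b0 + slope * auc)).astype(int)
        if y.min() == y.max():
            failed += 1
            continue
        fit = ExposureLogitModel(auc, y).fit()
        rows.append({"estimate": fit.odds_ratio, "ci_low": fit.or_ci[0],
                     "ci_high": fit.or_ci[1]})
    return RecoveryResult(pd.DataFrame(rows), or_per_unit, failed)


def cox_hr_recovery(
    n: int = 123,
    hr_per_unit: float = 1.03,
    baseline_median_days: float = 730.0,
    censor_days: float = 1095.0,
    n_rep: int = 500,
    seed: int = 0,
    auc_ref: float = AUC_GM,
) -> RecoveryResult:
    """Recovery of a static-exposure Cox hazard ratio per 1 ug·h/mL under
    an exponential baseline with administrative censoring."""
    beta = np.log(hr_per_unit)
    lam0 = np.log(2.0) / baseline_median_days
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_rep):
        auc = draw_auc(rng, n)
        lam = lam0 * np.exp(beta * (auc - auc_ref))
        t = rng.exponential(1.0 / lam)
        event = (t <= censor_days).astype(int)
        t = np.minimum(t, censor_days)
        df = pd.DataFrame({"time": t, "event": event, "exposure": auc})
        fit = ExposureCoxModel(df).fit()
        rows.append({"estimate": fit.hazard_ratio, "ci_low": fit.hr_ci[0],
                     "ci_high": fit.hr_ci[1]})
    return RecoveryResult(pd.DataFrame(rows), hr_per_unit)


def confounded_null_simulation(
    n: int = 123,
    n_rep: int = 300,
    seed: int = 0,
    pfs_median_days: float = 730.0,
    reduction_median_days: float = 730.0,
    censor_days: float = 1095.0,
    full_dose: float = 180.0,
    reduced_dose: float = 120.0,
) -> pd.DataFrame:
    """Static versus time-varying Cox under an exposure-independent
    hazard with dose reductions.

    Progression is exponential and independent of exposure; every subject
    starts at the full dose and may step down once at an exponential
    reduction time, so longer survivors are more likely to spend time at
    reduced exposure.  The static metric (time-averaged daily AUC to the
    event) therefore correlates negatively with survival, biasing the
    static fit toward hazard ratios above 1, while the time-varying fit
    sees the current exposure and stays centred on the null.

    Returns one row per replicate: static and time-varying HR estimates
    with their CIs.
    """
    lam_pfs = np.log(2.0) / pfs_median_days
    lam_red = np.log(2.0) / reduction_median_days
    sigma = lognormal_auc_sigma()
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_rep):
        cl_mult = np.exp(rng.normal(0.0, sigma, n))  # AUC ~ lognormal
        t_ev = rng.exponential(1.0 / lam_pfs, n)
        event = (t_ev <= censor_days).astype(int)
        t_ev = np.ceil(np.minimum(t_ev, censor_days))
        t_red = rng.exponential(1.0 / lam_red, n)
        static, series = np.empty(n), {}
        for i in range(n):
            days = int(t_ev[i])
            auc_full = full_dose / 180.0 * AUC_GM * cl_mult[i]
            auc_red = reduced_dose / 180.0 * AUC_GM * cl_mult[i]
            red_day = int(np.ceil(t_red[i]))
            vals = np.full(days, auc_full)
            if red_day < days:
                vals[red_day:] = auc_red
            static[i] = vals.mean()
            series[i + 1] = DailyExposureSeries(vals)
        tte = pd.DataFrame({"subject": np.arange(1, n + 1),
                            "time": t_ev, "event": event})
        st = ExposureCoxModel(
            pd.DataFrame({"time": t_ev, "event": event, "exposure": static})
        ).fit()
        tv = ExposureTimeVaryingCoxModel(series, tte).fit()
        rows.append({
            "static_hr": st.hazard_ratio,
            "static_lo": st.hr_ci[0], "static_hi": st.hr_ci[1],
            "tv_hr": tv.hazard_ratio,
            "tv_lo": tv.hr_ci[0], "tv_hi": tv.hr_ci[1],
        })
    return pd.DataFrame(rows)
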