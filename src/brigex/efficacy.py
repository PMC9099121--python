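"""Exposure-efficacy models.

Progression-free survival is related to exposure through proportional
hazards models, lambda(t) = lambda0(t) * exp(beta' X), fitted by maximum
partial likelihood with Efron tie handling: a static variant with one
exposure summary per subject, and a time-varying variant in which the
daily AUC series enters as a time-dependent covariate on counting-process
(start, stop] intervals.  Response endpoints (ORR, iORR) are related to
static exposure by logistic regression; perfect separation falls back to
a Firth-penalised fit.  Kaplan-Meier summaries stratified by exposure
quartile complete the descriptive picture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from scipy import stats

__all__ = [
    "CoxFitResult",
    "LogisticFitResult",
    "ExposureCoxModel",
    "ExposureTimeVaryingCoxModel",
    "ExposureLogitModel",
    "km_by_exposure_quartile",
    "KMStrata",
]


@dataclass
class CoxFitResult:
    """Proportional-hazards fit: per-term estimates and the partial
    log-likelihood.  ``terms`` rows: coef, hr, ci_low, ci_high, p."""

    terms: pd.DataFrame
    log_likelihood: float
    exposure_term: str
    model: object = field(repr=False, default=None)

    @property
    def hazard_ratio(self) -> float:
        return float(self.terms.loc[self.exposure_term, "hr"])

    @property
    def hr_ci(self) -> tuple:
        row = self.terms.loc[self.exposure_term]
        return (float(row["ci_low"]), float(row["ci_high"]))

    @property
    def p_value(self) -> float:
        return float(self.terms.loc[self.exposure_term, "p"])

    def summary(self) -> pd.DataFrame:
        return self.terms.copy()


@dataclass
class LogisticFitResult:
    """Logistic exposure-response fit (odds ratio per 1 ug·h/mL)."""

    intercept: float
    slope: float
    slope_se: float
    odds_ratio: float
    or_ci: tuple
    p_value: float
    log_likelihood: float
    firth: bool = False
    extra_terms: pd.DataFrame | None = None

    def predict(self, exposure) -> np.ndarray:
        """Predicted response probability at the given exposure(s)."""
        x = np.asarray(exposure, dtype=float)
        return 1.0 / (1.0 + np.exp(-(self.intercept + self.slope * x)))

    def summary(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "estimate": [self.intercept, self.slope],
                "odds_ratio": [np.nan, self.odds_ratio],
                "ci_low": [np.nan, self.or_ci[0]],
                "ci_high": [np.nan, self.or_ci[1]],
                "p": [np.nan, self.p_value],
            },
            index=["intercept", "exposure"],
        )
        return rows


def _cox_result_from_lifelines(fitter, exposure_term: str) -> CoxFitResult:
    s = fitter.summary
    terms = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxFitResult(terms, float(fitter.log_likelihood_), exposure_term, fitter)


class ExposureCoxModel:
    """Static-exposure Cox proportional hazards model.

    ``data`` must contain one row per subject with ``duration_col`` (days),
    ``event_col`` (1 = progression/death, 0 = censored), ``exposure_col``
    and any additional covariate columns listed in ``covariates``.
    """

    def __init__(self, data: pd.DataFrame, duration_col="time", event_col="event",
                 exposure_col="exposure", covariates=()):
        if data[event_col].sum() < 1:
            raise ValueError("at least one event is required")
        if not np.all(np.isfinite(data[exposure_col])):
            raise ValueError("exposures must be finite")
        if np.any(data[duration_col] <= 0):
            raise ValueError("event/censoring times must be positive")
        self.data = data
        self.duration_col = duration_col
        self.event_col = event_col
        self.exposure_col = exposure_col
        self.covariates = list(covariates)

    def fit(self) -> CoxFitResult:
        cols = [self.duration_col, self.event_col, self.exposure_col] + self.covariates
        df = self.data[cols]
        design = df[[self.exposure_col] + self.covariates]
        rank = np.linalg.matrix_rank(design.to_numpy() - design.to_numpy().mean(0))
        if rank < design.shape[1]:
            warnings.warn("collinear predictors detected in Cox design")
        cph = CoxPHFitter()  # Efron tie handling (lifelines default)
        cph.fit(df, duration_col=self.duration_col, event_col=self.event_col)
        return _cox_result_from_lifelines(cph, self.exposure_col)


class ExposureTimeVaryingCoxModel:
    """Time-varying exposure Cox model on counting-process intervals.

    Built from per-subject daily exposure series: consecutive days with
    equal exposure are merged into maximal constant spans (identical
    partial likelihood, far fewer rows).  A series shorter than follow-up
    has its last value carried forward (flagged).
    """

    def __init__(self, series_by_subject: dict, tte: pd.DataFrame,
                 covariates_by_subject: pd.DataFrame | None = None,
                 exposure_col: str = "exposure"):
        """``tte`` columns: subject, time (days), event."""
        self.series_by_subject = series_by_subject
        self.tte = tte
        self.covariates = covariates_by_subject
        self.exposure_col = exposure_col

    def build_intervals(self) -> pd.DataFrame:
        rows = []
        carried = False
        for rec in self.tte.itertuples(index=False):
            sid, t_end, ev = rec.subject, float(rec.time), int(rec.event)
            series = self.series_by_subject[sid]
            vals = np.asarray(series.auc, dtype=float)
            n_days = int(np.ceil(t_end))
            if len(vals) < n_days:
                carried = True
                pad = np.full(n_days - len(vals), vals[-1] if len(vals) else 0.0)
                vals = np.concatenate([vals, pad])
            vals = vals[:n_days]
            # merge equal-exposure days into maximal constant spans
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change]).astype(float)
            stops = np.concatenate([change, [n_days]]).astype(float)
            stops[-1] = t_end
            for a, b, v in zip(starts, stops, vals[starts.astype(int)]):
                if b <= a:
                    continue
                rows.append(
                    {"subject": sid, "start": a, "stop": b,
                     self.exposure_col: v, "event": 0}
                )
            rows[-1]["event"] = ev
        if carried:
            warnings.warn("exposure series shorter than follow-up; last value "
                          "carried forward")
        df = pd.DataFrame(rows)
        if self.covariates is not None:
            df = df.merge(self.covariates, on="subject", how="left")
        return df

    def fit(self) -> CoxFitResult:
        df = self.build_intervals()
        ctv = CoxTimeVaryingFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(df, id_col="subject", event_col="event",
                    start_col="start", stop_col="stop")
        return _cox_result_from_lifelines(ctv, self.exposure_col)


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter=200, tol=1e-10):
    """Firth-penalised logistic regression (Jeffreys-prior score
    correction); returns (beta, cov, penalised log-likelihood)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        cov = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, cov, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    sign, logdet = np.linalg.slogdet(X.T @ (X * (p * (1 - p))[:, None]))
    return beta, cov, ll + 0.5 * logdet


class ExposureLogitModel:
    """Logistic regression of a binary response on a static exposure
    metric (plus optional covariates); reports the odds ratio per
    1 ug·h/mL with a Wald CI on the log scale."""

    def __init__(self, exposure, response, covariates: pd.DataFrame | None = None):
        self.exposure = np.asarray(exposure, dtype=float)
        self.response = np.asarray(response, dtype=int)
        if set(np.unique(self.response)) - {0, 1}:
            raise ValueError("response must be binary 0/1")
        if self.response.min() == self.response.max():
            raise ValueError("both response classes must be present")
        self.covariates = covariates

    def _design(self):
        cols = [np.ones_like(self.exposure), self.exposure]
        names = ["intercept", "exposure"]
        if self.covariates is not None:
            for c in self.covariates.columns:
                cols.append(self.covariates[c].to_numpy(dtype=float))
                names.append(c)
        return np.column_stack(cols), names

    def fit(self) -> LogisticFitResult:
        import statsmodels.api as sm

        X, names = self._design()
        y = self.response
        firth = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta = res.params
            cov = res.cov_params()
            ll = float(res.llf)
            if not np.all(np.isfinite(np.sqrt(np.diag(cov)))) or np.abs(beta[1]) > 25:
                raise np.linalg.LinAlgError("separation suspected")
        except Exception:
            warnings.warn("separation detected; Firth-penalised fallback used")
            firth = True
            beta, cov, ll = _firth_logistic(X, y)
        se = np.sqrt(np.diag(cov))
        z = stats.norm.ppf(0.975)
        slope, sse = float(beta[1]), float(se[1])
        pval = 2 * stats.norm.sf(abs(slope) / sse) if sse > 0 else np.nan
        extra = None
        if len(names) > 2:
            extra = pd.DataFrame(
                {"coef": beta[2:], "se": se[2:],
                 "p": 2 * stats.norm.sf(np.abs(beta[2:]) / se[2:])},
                index=names[2:],
            )
        return LogisticFitResult(
            intercept=float(beta[0]),
            slope=slope,
            slope_se=sse,
            odds_ratio=float(np.exp(slope)),
            or_ci=(float(np.exp(slope - z * sse)), float(np.exp(slope + z * sse))),
            p_value=float(pval),
            log_likelihood=ll,
            firth=firth,
            extra_terms=extra,
        )


def fit_logistic_response(exposure, response) -> LogisticFitResult:
    """Functional shorthand for ``ExposureLogitModel(...).fit()``."""
    return ExposureLogitModel(exposure, response).fit()


@dataclass
class KMStrata:
    """Kaplan-Meier fits per exposure stratum."""

    fitters: dict  # stratum label -> KaplanMeierFitter
    medians: dict  # stratum label -> median (np.inf when not reached)
    counts: dict
    assignment: np.ndarray

    def median_table(self) -> pd.DataFrame:
        rows = []
        for lab in self.fitters:
            med = self.medians[lab]
            rows.append(
                {"stratum": lab, "n": self.counts[lab],
                 "median": med if np.isfinite(med) else np.nan,
                 "median_reached": bool(np.isfinite(med))}
            )
        return pd.DataFrame(rows)

    def plot(self, ax=None, comparator: pd.DataFrame | None = None):
        """KM step plot; ``comparator`` optionally supplies an externally
        provided (time, survival) curve to overlay — plotted only."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        for lab, km in self.fitters.items():
            km.plot_survival_function(ax=ax, ci_show=False, label=str(lab))
        if comparator is not None:
            ax.step(comparator["time"], comparator["survival"], where="post",
                    color="k", ls="--", label="comparator arm")
        ax.set_xlabel("time (days)")
        ax.set_ylabel("survival probability")
        ax.legend(frameon=False)
        return ax


def assign_quartiles(exposure, n_groups: int = 4) -> np.ndarray:
    """Empirical-quantile group index (0-based); values exactly on a
    boundary go to the lower group."""
    x = np.asarray(exposure, dtype=float)
    qs = np.quantile(x, np.arange(1, n_groups) / n_groups)
    return np.searchsorted(qs, x, side="left")


def km_by_exposure_quartile(
    exposure, durations, events, n_groups: int = 4, labels=None
) -> KMStrata:
    """Kaplan-Meier estimates stratified by exposure quartile.

    Medians are the first time survival drops to <= 0.5; strata whose
    curve never crosses 0.5 report an infinite (not-reached) median.
    """
    x = np.asarray(exposure, dtype=float)
    if len(x) < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} subjects")
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    groups = assign_quartiles(x, n_groups)
    if labels is None:
        labels = [f"Q{g + 1}" for g in range(n_groups)]
    fitters, medians, counts = {}, {}, {}
    for g in range(n_groups):
        sel = groups == g
        km = KaplanMeierFitter(label=labels[g])
        km.fit(t[sel], e[sel])
        fitters[labels[g]] = km
        medians[labels[g]] = float(km.median_survival_time_)
        counts[labels[g]] = int(sel.sum())
    return KMStrata(fitters, medians, counts, groups)
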