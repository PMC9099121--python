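"""Covariate analysis.

Two facilities: stepwise covariate selection on a significant
exposure-response model (forward addition at p < 0.05, backward
elimination at p > 0.01, likelihood-ratio tests, exposure never removed),
and the covariate-exposure forest summary (per-covariate linear
regressions of log steady-state AUC with predicted-exposure ratios at
covariate percentiles or category levels versus the reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    kind: str  # "continuous" | "categorical"
    percentiles: tuple = (5.0, 95.0)  # continuous: percentiles of interest

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError("kind must be 'continuous' or 'categorical'")


def _impute(col: pd.Series, kind: str) -> pd.Series:
    """Median (continuous) / mode (categorical) imputation, flagged."""
    if col.isna().any():
        warnings.warn(f"covariate {col.name!r}: missing values imputed")
        fill = col.median() if kind == "continuous" else col.mode().iloc[0]
        col = col.fillna(fill)
    return col


def _expand(data: pd.DataFrame, spec: CovariateSpec) -> tuple:
    """Columns (dummy-coded for categoricals, reference = most common
    level) ready to enter a model."""
    col = _impute(data[spec.name], spec.kind)
    if spec.kind == "continuous":
        return pd.DataFrame({spec.name: col.astype(float)}), [spec.name]
    ref = col.value_counts().idxmax()
    levels = [lv for lv in col.value_counts().index if lv != ref]
    dummies = pd.DataFrame(
        {f"{spec.name}[{lv}]": (col == lv).astype(float) for lv in levels}
    )
    return dummies, list(dummies.columns)


@dataclass
class StepwiseResult:
    selected: list
    trace: pd.DataFrame
    final_fit: object


def stepwise_select(
    fit_fn,
    data: pd.DataFrame,
    candidates,
    p_in: float = 0.05,
    p_out: float = 0.01,
) -> StepwiseResult:
    """Forward-addition / backward-elimination covariate selection.

    ``fit_fn(data, covariate_columns)`` must fit the base exposure model
    augmented with the given columns and return an object exposing
    ``log_likelihood``.  At each forward step the candidate with the
    smallest likelihood-ratio p below ``p_in`` enters (ties broken
    alphabetically); backward steps drop included covariates whose LRT p
    exceeds ``p_out``.  The exposure term is part of the base model and is
    never eligible for removal.  Candidates whose fit fails are skipped
    and logged in the trace.
    """
    work = data.copy()
    blocks = {}
    for spec in candidates:
        cols_df, cols = _expand(work, spec)
        for c in cols_df.columns:
            work[c] = cols_df[c]
        blocks[spec.name] = cols

    def loglik(cov_cols):
        return fit_fn(work, cov_cols)

    included: list = []
    trace_rows = []
    base_fit = loglik([])
    current_ll = base_fit.log_likelihood
    current_fit = base_fit
    step = 0
    improved = True
    while improved:
        improved = False
        # forward
        tested = []
        for name in sorted(set(blocks) - set(included)):
            cols = sum((blocks[n] for n in included + [name]), [])
            try:
                fit = loglik(cols)
            except Exception as exc:  # non-converging candidate: skip, log
                trace_rows.append(
                    {"step": step, "action": "forward-failed", "term": name,
                     "p": np.nan, "note": str(exc)[:80]}
                )
                continue
            df_delta = len(blocks[name])
            p = stats.chi2.sf(2 * (fit.log_likelihood - current_ll), df_delta)
            trace_rows.append(
                {"step": step, "action": "forward-test", "term": name,
                 "p": p, "note": ""}
            )
            tested.append((p, name, fit))
        tested = [t for t in tested if t[0] < p_in]
        if tested:
            tested.sort(key=lambda t: (t[0], t[1]))  # lowest p, then name
            p, name, fit = tested[0]
            included.append(name)
            current_ll, current_fit = fit.log_likelihood, fit
            trace_rows.append(
                {"step": step, "action": "add", "term": name, "p": p, "note": ""}
            )
            improved = True
        step += 1
        # backward
        removed = True
        while removed and included:
            removed = False
            worst = None
            for name in sorted(included):
                cols = sum((blocks[n] for n in included if n != name), [])
                fit = loglik(cols)
                p = stats.chi2.sf(2 * (current_ll - fit.log_likelihood),
                                  len(blocks[name]))
                trace_rows.append(
                    {"step": step, "action": "backward-test", "term": name,
                     "p": p, "note": ""}
                )
                if p > p_out and (worst is None or p > worst[0]):
                    worst = (p, name, fit)
            if worst is not None:
                p, name, fit = worst
                included.remove(name)
                current_ll, current_fit = fit.log_likelihood, fit
                trace_rows.append(
                    {"step": step, "action": "drop", "term": name, "p": p,
                     "note": ""}
                )
                removed = True
                improved = True
            step += 1
    return StepwiseResult(included, pd.DataFrame(trace_rows), current_fit)


def exposure_covariate_forest(
    auc: pd.Series,
    covariates: pd.DataFrame,
    specs,
    typical_auc: float | None = None,
    ci_level: float = 0.90,
) -> pd.DataFrame:
    """Per-covariate linear regressions of log(AUC) with predicted-AUC
    ratios.

    Continuous covariates report the ratio of predicted AUC at their 5th
    and 95th percentiles versus the median; categorical covariates report
    each level versus the reference (most common) level; each with a 90%
    CI.  A final row gives the overall 5th-95th percentile AUC range as
    ratios to the typical-patient AUC.  Constant covariates are skipped.
    """
    if len(auc) < 10:
        raise ValueError("at least 10 subjects required")
    import statsmodels.api as sm

    log_auc = np.log(np.asarray(auc, dtype=float))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    rows = []
    for spec in specs:
        col = _impute(covariates[spec.name], spec.kind)
        if col.nunique() < 2:
            warnings.warn(f"constant covariate {spec.name!r} skipped")
            continue
        if spec.kind == "continuous":
            x = col.to_numpy(dtype=float)
            X = sm.add_constant(x)
            fit = sm.OLS(log_auc, X).fit()
            beta, se = fit.params[1], fit.bse[1]
            med = np.median(x)
            for pct in spec.percentiles:
                delta = np.percentile(x, pct) - med
                rows.append(
                    {"covariate": spec.name, "level": f"p{pct:g} vs median",
                     "ratio": np.exp(beta * delta),
                     "ci_low": np.exp((beta - z * se) * delta) if delta >= 0
                               else np.exp((beta + z * se) * delta),
                     "ci_high": np.exp((beta + z * se) * delta) if delta >= 0
                                else np.exp((beta - z * se) * delta)}
                )
        else:
            ref = col.value_counts().idxmax()
            levels = [lv for lv in col.value_counts().index if lv != ref]
            dummies = np.column_stack([(col == lv).astype(float) for lv in levels])
            X = sm.add_constant(dummies)
            fit = sm.OLS(log_auc, X).fit()
            for j, lv in enumerate(levels):
                beta, se = fit.params[1 + j], fit.bse[1 + j]
                rows.append(
                    {"covariate": spec.name, "level": f"{lv} vs {ref}",
                     "ratio": np.exp(beta),
                     "ci_low": np.exp(beta - z * se),
                     "ci_high": np.exp(beta + z * se)}
                )
    ref_auc = typical_auc if typical_auc is not None else float(np.exp(np.median(log_auc)))
    lo, hi = np.percentile(np.exp(log_auc), [5, 95])
    rows.append(
        {"covariate": "overall", "level": "p5-p95 vs typical",
         "ratio": np.nan, "ci_low": lo / ref_auc, "ci_high": hi / ref_auc}
    )
    return pd.DataFrame(rows)


def plot_forest(forest: pd.DataFrame, ax=None):
    import matplotlib.pyplot as plt

    body = forest[forest["covariate"] != "overall"]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(body) + 1.5))
    ypos = np.arange(len(body))[::-1]
    ax.errorbar(
        body["ratio"], ypos,
        xerr=[body["ratio"] - body["ci_low"], body["ci_high"] - body["ratio"]],
        fmt="o", color="C0", capsize=2,
    )
    ax.axvline(1.0, color="k", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(body["covariate"] + ": " + body["level"])
    ax.set_xlabel("exposure ratio vs reference")
    return ax
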