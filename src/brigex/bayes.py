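"""MAP (empirical Bayes) estimation of individual random effects, with the
population model fixed as the prior, and residual diagnostics.

The individual objective is the standard -2 log-posterior up to a constant:

    OFV(eta) = sum_obs [ (y - f)^2 / g + ln g ] + eta' Omega^-1 eta,

with f the model prediction at the individual parameters implied by eta
and g = (sigma_prop * f)^2 + sigma_add^2 the combined residual variance.
Observations below the limit of quantification are excluded.  With no
quantifiable observations the prior mode (eta = 0) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import ETA_NAMES, IndividualPKParameters, PopPKParameters, apply_covariates_and_eta
from .pkmodel import simulate_concentrations
from .records import SubjectRecord

# Fixed sub-seed for the jittered multi-start scheme: MAP estimates are a
# deterministic function of (population model, subject data).
_MULTISTART_SEED = 20_220_208
_N_JITTER = 4


@dataclass
class MAPResult:
    """Result of a single-subject MAP fit."""

    eta_hat: np.ndarray
    ind_params: IndividualPKParameters
    objective: float
    n_obs: int
    converged: bool = True
    all_blq: bool = False

    def summary(self) -> pd.DataFrame:
        rows = {f"eta_{n}": v for n, v in zip(ETA_NAMES, self.eta_hat)}
        for name in ("cl", "v1", "q2", "v2", "q3", "v3", "n_transit", "mtt"):
            rows[name] = getattr(self.ind_params, name)
        rows["objective"] = self.objective
        rows["n_obs"] = self.n_obs
        return pd.DataFrame({"value": rows})


def _objective_factory(pop: PopPKParameters, subject: SubjectRecord):
    obs = subject.quantifiable()
    times = np.array([o.time for o in obs])
    order = np.argsort(times)
    times = times[order]
    y = np.array([o.value for o in obs])[order]
    omega_inv = np.linalg.pinv(pop.omega)

    def objective(eta):
        ind = apply_covariates_and_eta(pop, subject.albumin, eta)
        f = simulate_concentrations(ind, subject.doses, times)
        g = (pop.sigma_prop * f) ** 2 + pop.sigma_add**2
        g = np.maximum(g, 1e-12)
        return float(np.sum((y - f) ** 2 / g + np.log(g)) + eta @ omega_inv @ eta)

    return objective, len(obs)


class IndividualBayesModel:
    """MAP Bayesian model for one subject's random effects.

    Parameters
    ----------
    pop : PopPKParameters
        Population prior (fixed effects, omega, residual error).
    subject : SubjectRecord
        Dosing history, concentration observations and albumin.
    """

    def __init__(self, pop: PopPKParameters, subject: SubjectRecord):
        self.pop = pop
        self.subject = subject

    def fit(self) -> MAPResult:
        objective, n_obs = _objective_factory(self.pop, self.subject)
        k = len(ETA_NAMES)
        if n_obs == 0:
            eta0 = np.zeros(k)
            ind = apply_covariates_and_eta(self.pop, self.subject.albumin, eta0)
            return MAPResult(eta0, ind, objective(eta0), 0, all_blq=True)
        # multi-start: the prior mode plus jittered starts with fixed seeds
        rng = np.random.default_rng(_MULTISTART_SEED)
        sd = np.sqrt(np.diag(self.pop.omega))
        starts = [np.zeros(k)]
        starts += [rng.standard_normal(k) * 0.5 * sd for _ in range(_N_JITTER)]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 400},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        # simplex polish from the best quasi-Newton solution
        res = optimize.minimize(
            objective, best.x, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        if res.fun < best.fun:
            best = res
        eta_hat = best.x
        # degenerate effects (zero omega variance) stay at the prior mode
        eta_hat = np.where(np.diag(self.pop.omega) > 0, eta_hat, 0.0)
        ind = apply_covariates_and_eta(self.pop, self.subject.albumin, eta_hat)
        return MAPResult(eta_hat, ind, float(best.fun), n_obs, bool(best.success))


def map_estimate(pop: PopPKParameters, subject: SubjectRecord) -> MAPResult:
    """Functional shorthand for ``IndividualBayesModel(pop, subject).fit()``."""
    return IndividualBayesModel(pop, subject).fit()


def _prediction_gradient(pop, subject, eta, times, h=1e-4):
    """Finite-difference gradient of predictions with respect to eta."""
    k = len(eta)
    grad = np.zeros((len(times), k))
    for j in range(k):
        ep = eta.copy(); ep[j] += h
        em = eta.copy(); em[j] -= h
        fp = simulate_concentrations(
            apply_covariates_and_eta(pop, subject.albumin, ep), subject.doses, times
        )
        fm = simulate_concentrations(
            apply_covariates_and_eta(pop, subject.albumin, em), subject.doses, times
        )
        grad[:, j] = (fp - fm) / (2 * h)
    return grad


def residual_diagnostics(
    pop: PopPKParameters, subjects, fits
) -> pd.DataFrame:
    """Per-observation residual table for fitted subjects.

    Emits individual weighted residuals IWRES = (y - f_ind)/sqrt(g(f_ind))
    and conditional weighted residuals computed by first-order conditional
    linearisation around eta_hat: the marginal mean is approximated by
    f(eta_hat) - G @ eta_hat and the marginal covariance by
    G Omega G' + diag(g), with G the prediction gradient at eta_hat;
    CWRES is the whitened residual under that approximation.
    """
    rows = []
    for subject, fit in zip(subjects, fits):
        obs = subject.quantifiable()
        if not obs:
            continue
        times = np.array(sorted(o.time for o in obs))
        y = np.array([o.value for o in sorted(obs, key=lambda o: o.time)])
        f_ind = simulate_concentrations(fit.ind_params, subject.doses, times)
        g = (pop.sigma_prop * f_ind) ** 2 + pop.sigma_add**2
        iwres = (y - f_ind) / np.sqrt(g)
        pred = simulate_concentrations(
            apply_covariates_and_eta(pop, subject.albumin, np.zeros(len(ETA_NAMES))),
            subject.doses, times,
        )
        G = _prediction_gradient(pop, subject, fit.eta_hat, times)
        mean = f_ind - G @ fit.eta_hat
        cov = G @ pop.omega @ G.T + np.diag(g)
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(times)))
        cwres = np.linalg.solve(L, y - mean)
        for t, yi, fi, pi, iw, cw in zip(times, y, f_ind, pred, iwres, cwres):
            rows.append(
                {
                    "subject": subject.subject_id,
                    "time": t,
                    "dv": yi,
                    "ipred": fi,
                    "pred": pi,
                    "iwres": iw,
                    "cwres": cw,
                }
            )
    return pd.DataFrame(rows)


def residual_normality_pvalue(diagnostics: pd.DataFrame) -> float:
    """Shapiro-Wilk p-value for the CWRES column (subsampled at large n)."""
    x = diagnostics["cwres"].to_numpy()
    if len(x) > 4000:
        x = x[:: len(x) // 4000 + 1]
    return float(stats.shapiro(x).pvalue)
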