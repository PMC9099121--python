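"""MAP Bayesian individual estimation and residual diagnostics."""

import numpy as np
import pytest

from brigex import (
    ConcObservation,
    DoseEvent,
    SubjectRecord,
    apply_covariates_and_eta,
    simulate_concentrations,
)
from brigex.bayes import (
    IndividualBayesModel,
    map_estimate,
    residual_diagnostics,
    residual_normality_pvalue,
)


def make_subject(pop, eta, rng, n_obs=24, horizon_days=14, sigma_prop=0.05,
                 sigma_add=0.5, sid=1, albumin=41.0):
    ind = apply_covariates_and_eta(pop, albumin, eta)
    doses = [DoseEvent(24.0 * i, 180.0) for i in range(horizon_days)]
    times = np.sort(rng.uniform(0.5, horizon_days * 24.0, n_obs))
    f = simulate_concentrations(ind, doses, times)
    y = f * (1 + rng.standard_normal(n_obs) * sigma_prop)
    y = y + rng.standard_normal(n_obs) * sigma_add
    obs = [ConcObservation(t, max(v, 0.0), blq=v < pop.lloq)
           for t, v in zip(times, y)]
    return SubjectRecord(sid, {"albumin": albumin}, doses, obs), ind


class TestMapEstimate:
    def test_no_observations_returns_prior_mode(self, pop):
        s = SubjectRecord(1, {"albumin": 38.0},
                          [DoseEvent(0.0, 90.0)], [])
        fit = map_estimate(pop, s)
        assert np.all(fit.eta_hat == 0)
        assert fit.all_blq
        assert fit.n_obs == 0
        typ = apply_covariates_and_eta(pop, 38.0, np.zeros(5))
        assert fit.ind_params.cl == pytest.approx(typ.cl)

    def test_all_blq_returns_prior_mode(self, pop):
        obs = [ConcObservation(1.0, 2.0, blq=True)]
        s = SubjectRecord(1, {"albumin": 41.0}, [DoseEvent(0.0, 90.0)], obs)
        fit = map_estimate(pop, s)
        assert np.all(fit.eta_hat == 0)
        assert fit.n_obs == 0

    def test_rich_sampling_recovers_clearance(self, pop):
        """Rich, low-noise sampling must recover individual CL within 10%."""
        rng = np.random.default_rng(11)
        low_noise = pop.with_overrides(sigma_prop=0.05, sigma_add=0.5)
        eta = np.array([0.35, -0.2, 0.15, 0.1, -0.25])
        subject, ind = make_subject(low_noise, eta, rng)
        fit = IndividualBayesModel(low_noise, subject).fit()
        assert fit.ind_params.cl == pytest.approx(ind.cl, rel=0.10)
        assert np.isfinite(fit.objective)

    def test_sparse_design_shrinks_toward_prior(self, pop):
        """Under sparse trial-like sampling the MAP eta vector is shrunk:
        averaged over subjects and components, |eta_hat| is below
        |eta_true| (poorly identified components collapse to the prior)."""
        rng = np.random.default_rng(3)
        chol = np.linalg.cholesky(pop.omega)
        sparse_times = [0.0, 672.0, 673.0, 676.0, 679.0, 1344.0, 1348.0]
        diffs = []
        for sid in range(30):
            eta = chol @ rng.standard_normal(5)
            ind = apply_covariates_and_eta(pop, 41.0, eta)
            doses = [DoseEvent(24.0 * i, 180.0) for i in range(60)]
            f = simulate_concentrations(ind, doses, np.array(sparse_times))
            y = f * (1 + rng.standard_normal(len(f)) * pop.sigma_prop)
            y = y + rng.standard_normal(len(f)) * pop.sigma_add
            obs = [ConcObservation(t, max(v, 0.0), blq=v < pop.lloq)
                   for t, v in zip(sparse_times, y)]
            s = SubjectRecord(sid, {"albumin": 41.0}, doses, obs)
            fit = IndividualBayesModel(pop, s).fit()
            diffs.append(np.mean(np.abs(fit.eta_hat)) - np.mean(np.abs(eta)))
        assert np.mean(diffs) < 0.0

    def test_diffuse_prior_approaches_mle_grid_oracle(self, pop):
        """With an essentially flat prior on eta_cl (others fixed) and
        rich data, the MAP estimate matches a grid-search maximum
        likelihood oracle on the 1-parameter reduction."""
        rng = np.random.default_rng(21)
        diffuse = pop.with_overrides(
            omega=np.diag([25.0, 0.0, 0.0, 0.0, 0.0]),
            sigma_prop=0.05, sigma_add=0.5,
        )
        eta = np.array([0.45, 0.0, 0.0, 0.0, 0.0])
        subject, ind = make_subject(diffuse, eta, rng, n_obs=30)
        fit = IndividualBayesModel(diffuse, subject).fit()
        # grid-search oracle over eta_cl only
        times = np.array([o.time for o in subject.quantifiable()])
        y = np.array([o.value for o in subject.quantifiable()])
        grid = np.linspace(-1.0, 1.5, 801)
        best, best_val = None, np.inf
        for e in grid:
            ind_e = apply_covariates_and_eta(
                diffuse, 41.0, np.array([e, 0, 0, 0, 0]))
            f = simulate_concentrations(ind_e, subject.doses, times)
            g = (0.05 * f) ** 2 + 0.5**2
            val = np.sum((y - f) ** 2 / g + np.log(g))
            if val < best_val:
                best, best_val = e, val
        assert fit.eta_hat[0] == pytest.approx(best, abs=0.02)
        assert np.all(fit.eta_hat[1:] == 0)  # degenerate effects stay fixed


class TestResidualDiagnostics:
    def test_noise_free_data_at_true_parameters_gives_zero_residuals(self, pop):
        """When the fitted parameters reproduce noise-free data exactly,
        all individual weighted residuals are zero."""
        from brigex.bayes import MAPResult

        rng = np.random.default_rng(5)
        eta = np.array([0.2, -0.1, 0.0, 0.1, 0.0])
        subject, ind = make_subject(pop, eta, rng, sigma_prop=0.0, sigma_add=0.0)
        exact = MAPResult(eta, ind, 0.0, len(subject.observations))
        table = residual_diagnostics(pop, [subject], [exact])
        assert np.max(np.abs(table["iwres"])) < 1e-8

    def test_model_consistent_data_residuals_look_normal(self, pop):
        """Data simulated from the model itself yield CWRES passing a
        Shapiro-type normality check at p > 0.01 (n ≈ 500)."""
        rng = np.random.default_rng(8)
        chol = np.linalg.cholesky(pop.omega)
        mod = pop.with_overrides(sigma_prop=0.15, sigma_add=1.0)
        subjects, fits = [], []
        for sid in range(18):
            eta = chol @ rng.standard_normal(5)
            subject, _ = make_subject(
                mod, eta, rng, n_obs=28, sigma_prop=0.15, sigma_add=1.0,
                sid=sid)
            subjects.append(subject)
            fits.append(IndividualBayesModel(mod, subject).fit())
        table = residual_diagnostics(mod, subjects, fits)
        assert len(table) >= 480
        assert residual_normality_pvalue(table) > 0.01

    def test_misspecified_clearance_leaves_residual_trend(self, pop):
        """A 2-fold misspecification of typical clearance produces a
        significant residual-versus-prediction trend."""
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        truth = pop.with_overrides(sigma_prop=0.10, sigma_add=0.5)
        wrong = pop.with_overrides(
            cl_typ=2 * pop.cl_typ, omega=np.diag([0.0, 0.0, 0.0, 0.0, 0.0]),
            sigma_prop=0.10, sigma_add=0.5,
        )
        subjects, fits = [], []
        for sid in range(10):
            subject, _ = make_subject(
                truth, np.zeros(5), rng, n_obs=20,
                sigma_prop=0.10, sigma_add=0.5, sid=sid)
            subjects.append(subject)
            fits.append(IndividualBayesModel(wrong, subject).fit())
        table = residual_diagnostics(wrong, subjects, fits)
        X = sm.add_constant(table["pred"].to_numpy())
        ols = sm.OLS(table["cwres"].to_numpy(), X).fit()
        assert ols.pvalues[1] < 0.01
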