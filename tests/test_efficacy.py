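"""Exposure-efficacy estimators: Cox (static and time-varying), logistic
response models and quartile-stratified Kaplan-Meier summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit, logit

from brigex.efficacy import (
    ExposureCoxModel,
    ExposureLogitModel,
    ExposureTimeVaryingCoxModel,
    assign_quartiles,
    km_by_exposure_quartile,
)
from brigex.exposure import DailyExposureSeries


class TestStaticCox:
    def test_three_subject_partial_likelihood_oracle(self):
        """Small worked example checked against a hand-written partial
        likelihood maximised numerically (closed form: exp(beta_hat) =
        1/sqrt(2) for this configuration)."""
        df = pd.DataFrame({
            "time": [1.0, 2.0, 3.0],
            "event": [1, 1, 1],
            "exposure": [1.0, 0.0, 1.0],
        })
        fit = ExposureCoxModel(df).fit()

        def neg_log_pl(b):
            # risk sets: {A,B,C} at t=1 (event A, x=1); {B,C} at t=2
            # (event B, x=0); {C} at t=3
            return -(b - np.log(2 * np.exp(b) + 1) + 0 - np.log(1 + np.exp(b)))

        oracle = optimize.minimize_scalar(neg_log_pl, bounds=(-5, 5),
                                          method="bounded").x
        assert fit.terms.loc["exposure", "coef"] == pytest.approx(oracle, abs=1e-3)
        assert fit.hazard_ratio == pytest.approx(1 / np.sqrt(2), abs=1e-3)

    def test_known_log_hazard_recovered(self):
        """Simulation at a known per-unit log hazard: the point estimate
        lands within Monte-Carlo error of truth."""
        from brigex.recovery import cox_hr_recovery

        res = cox_hr_recovery(n=123, hr_per_unit=1.05, n_rep=60, seed=4)
        assert res.mean_estimate == pytest.approx(1.05, abs=3 * res.mc_se + 0.005)

    def test_null_exposure_ci_covers_one(self):
        """Randomly permuted exposure: the 95% CI covers HR = 1 in about
        95% of replicates."""
        rng = np.random.default_rng(12)
        cover = []
        for _ in range(120):
            n = 120
            auc = np.exp(rng.normal(np.log(21.3), 0.45, n))
            t = rng.exponential(500, n)
            ev = (t <= 700).astype(int)
            t = np.minimum(t, 700)
            df = pd.DataFrame({"time": t, "event": ev,
                               "exposure": rng.permutation(auc)})
            fit = ExposureCoxModel(df).fit()
            lo, hi = fit.hr_ci
            cover.append(lo <= 1.0 <= hi)
        assert np.mean(cover) == pytest.approx(0.95, abs=0.05)

    def test_requires_events_and_finite_exposure(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0],
                           "exposure": [1.0, 2.0]})
        with pytest.raises(ValueError):
            ExposureCoxModel(df)
        df2 = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0],
                            "exposure": [np.inf, 2.0]})
        with pytest.raises(ValueError):
            ExposureCoxModel(df2)


class TestTimeVaryingCox:
    def test_constant_series_equals_static_fit(self):
        """A constant exposure series must reproduce the static estimate
        exactly (identical partial likelihood)."""
        rng = np.random.default_rng(5)
        n = 60
        auc = np.exp(rng.normal(np.log(21.3), 0.45, n))
        t = np.ceil(rng.exponential(300, n))
        ev = (t <= 400).astype(int)
        t = np.minimum(t, 400.0)
        static = ExposureCoxModel(
            pd.DataFrame({"time": t, "event": ev, "exposure": auc})).fit()
        series = {i + 1: DailyExposureSeries(np.full(int(t[i]), auc[i]))
                  for i in range(n)}
        tte = pd.DataFrame({"subject": np.arange(1, n + 1),
                            "time": t, "event": ev})
        tv = ExposureTimeVaryingCoxModel(series, tte).fit()
        # same partial likelihood: optima agree to solver precision
        assert tv.log_likelihood == pytest.approx(static.log_likelihood, abs=1e-6)
        assert tv.terms.loc["exposure", "coef"] == pytest.approx(
            static.terms.loc["exposure", "coef"], abs=1e-4)

    def test_current_exposure_hazard_recovered(self):
        """Hazard depending on the current daily AUC: the time-varying
        fit recovers the generating coefficient."""
        rng = np.random.default_rng(6)
        beta = np.log(1.04)
        ests = []
        for _ in range(25):
            n = 150
            series, times, events = {}, [], []
            for i in range(n):
                base = np.exp(rng.normal(np.log(21.3), 0.45))
                vals = np.full(600, base)
                red = int(rng.integers(50, 500))
                vals[red:] = base * 2 / 3  # dose reduction
                lam = np.log(2) / 500 * np.exp(beta * (vals - 21.3))
                u = rng.random(600)
                hit = np.nonzero(u < 1 - np.exp(-lam))[0]
                if len(hit):
                    tt, evi = float(hit[0] + 1), 1
                else:
                    tt, evi = 600.0, 0
                series[i + 1] = DailyExposureSeries(vals[: int(tt)])
                times.append(tt)
                events.append(evi)
            tte = pd.DataFrame({"subject": np.arange(1, n + 1),
                                "time": times, "event": events})
            fit = ExposureTimeVaryingCoxModel(series, tte).fit()
            ests.append(fit.terms.loc["exposure", "coef"])
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(beta, abs=3 * se + 0.002)

    def test_reduction_in_long_survivors_biases_static_only(self):
        """Dose reductions concentrated in long survivors with an
        exposure-independent hazard: the static fit drifts above HR 1
        while the time-varying fit stays centred on the null."""
        from brigex.recovery import confounded_null_simulation

        df = confounded_null_simulation(n=123, n_rep=40, seed=9,
                                        reduction_median_days=300.0)
        assert df["static_hr"].mean() > 1.0
        tv_cover = ((df["tv_lo"] <= 1.0) & (1.0 <= df["tv_hi"])).mean()
        assert tv_cover == pytest.approx(0.95, abs=0.08)
        assert abs(np.log(df["tv_hr"]).mean()) < abs(np.log(df["static_hr"]).mean())


class TestLogisticResponse:
    def test_known_slope_recovered_and_prediction_curve(self):
        rng = np.random.default_rng(30)
        n = 2000
        x = np.exp(rng.normal(np.log(21.3), 0.45, n))
        slope = np.log(1.13)
        b0 = logit(0.83) - slope * 21.3
        y = (rng.random(n) < expit(b0 + slope * x)).astype(int)
        fit = ExposureLogitModel(x, y).fit()
        assert fit.odds_ratio == pytest.approx(1.13, abs=0.03)
        assert fit.predict(21.3) == pytest.approx(0.83, abs=0.03)

    def test_odds_ratio_per_unit_identity(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(5, 45, 300)
        y = (rng.random(300) < expit(-2 + 0.1 * x)).astype(int)
        fit = ExposureLogitModel(x, y).fit()
        p1, p2 = fit.predict([10.0, 11.0])
        odds_ratio = (p2 / (1 - p2)) / (p1 / (1 - p1))
        assert odds_ratio == pytest.approx(fit.odds_ratio, abs=1e-10)

    def test_null_slope_ci_covers_one(self):
        rng = np.random.default_rng(32)
        cover = []
        for _ in range(200):
            x = np.exp(rng.normal(np.log(21.3), 0.45, 123))
            y = (rng.random(123) < 0.4).astype(int)
            fit = ExposureLogitModel(x, y).fit()
            cover.append(fit.or_ci[0] <= 1.0 <= fit.or_ci[1])
        assert np.mean(cover) == pytest.approx(0.95, abs=0.04)

    def test_separation_triggers_firth_fallback(self):
        x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning):
            fit = ExposureLogitModel(x, y).fit()
        assert fit.firth
        assert np.isfinite(fit.odds_ratio)
        assert 0 < fit.predict(6.5) < 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ExposureLogitModel([1.0, 2.0], [1, 1])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        t = np.array([5.0, 10.0, 15.0, 20.0] * 4)
        e = np.ones(16, dtype=int)
        x = np.arange(16.0)
        strata = km_by_exposure_quartile(x, t, e)
        km = strata.fitters["Q1"]
        sf = km.survival_function_.iloc[:, 0]
        assert sf.loc[5.0] == pytest.approx(0.75)
        assert sf.loc[20.0] == pytest.approx(0.0)

    def test_half_events_at_ten_gives_median_ten(self):
        t = np.array([10.0, 10.0, 50.0, 50.0] * 4)
        e = np.array([1, 1, 0, 0] * 4)
        x = np.arange(16.0)
        strata = km_by_exposure_quartile(x, t, e, n_groups=1, labels=["all"])
        km = strata.fitters["all"]
        assert km.survival_function_.iloc[:, 0].loc[10.0] == pytest.approx(0.5)
        assert strata.medians["all"] == pytest.approx(10.0)

    def test_not_reached_median_is_infinite(self):
        t = np.full(16, 100.0)
        e = np.zeros(16, dtype=int)
        e[0] = 1
        strata = km_by_exposure_quartile(np.arange(16.0), t, e,
                                         n_groups=1, labels=["all"])
        assert not np.isfinite(strata.medians["all"])
        assert strata.median_table()["median_reached"].iloc[0] == False  # noqa: E712

    def test_quartile_sizes_balanced(self):
        rng = np.random.default_rng(40)
        x = rng.lognormal(3, 0.4, 123)
        groups = assign_quartiles(x)
        counts = np.bincount(groups, minlength=4)
        assert counts.sum() == 123
        assert counts.max() - counts.min() <= 2

    def test_boundary_ties_go_to_lower_quartile(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])
        groups = assign_quartiles(x)
        thresholds = np.quantile(x, [0.25, 0.5, 0.75])
        for xi, g in zip(x, groups):
            if xi in thresholds:
                assert g == np.searchsorted(thresholds, xi, side="left")
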