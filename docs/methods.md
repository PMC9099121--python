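# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind the package, and what the synthetic cohort does
and does not establish about real data.

## Structural PK model

Brigatinib disposition is a mammillary three-compartment system with
linear elimination from the central compartment. Absorption is
first-order (rate constant `ka`) from a depot fed by a continuous
transit-compartment chain: the input rate after a dose D at time 0 is
the gamma density `D·ktr(ktr t)^n e^{−ktr t}/Γ(n+1)` with
`ktr = (n+1)/MTT`. The continuous form is required because the estimated
transit count is non-integer (2.76). All parameters are apparent (/F);
bioavailability is fixed at 1.

Concentrations are evaluated semi-analytically. The depot + disposition
system is linear with constant coefficients, so the central-compartment
response to a depot bolus is a sum of four exponentials obtained by
eigendecomposition. The convolution of each exponential mode with the
gamma input density has the closed form
`(ktr/μ)^{n+1} e^{−λt} P(n+1, μt)` with `μ = ktr − λ` and `P` the
regularised lower incomplete gamma function, evaluated in log space;
the `μ → 0` limit is series-expanded, and the rare `μ < 0` case (a
disposition mode faster than the transit rate) falls back to fixed
Gauss–Legendre quadrature of the bounded integrand. Multiple doses
superpose exactly. An LSODA-based ODE integrator provides an independent
numerical route used in cross-validation tests; the two agree to better
than 1e-5 relative.

### Parameter defaults

Typical values (geometric means) and the covariate model are fixed to
the first-line population estimates: CL/F 8.45 L/h, V1/F 160 L, Q2/F
12.6 L/h, V2/F 118 L, Q3/F 2.67 L/h, V3/F 78.5 L, transit count 2.76,
MTT 1.01 h, with albumin (g/L) as a power covariate on CL/F normalised
at 41 g/L. Three defaults are not printed in any available source and
are package choices, all overridable via the YAML parameter file:

- **ka = 2.0 1/h.** The published model has first-order absorption after
  the transit chain but its rate is not reported here. 2.0 1/h gives a
  time of maximum concentration near 2 h, consistent with rapid oral
  absorption; with MTT ≈ 1 h the profile shape is dominated by the
  transit delay, so exposure metrics (which depend on CL only) are
  insensitive to this choice.
- **Ω (diagonal).** Log-scale SDs 0.45 (CL), 0.45 (V1), 0.55 (V2),
  0.35 (transit count), 0.45 (MTT), calibrated once from the reported
  5th–95th percentile spreads of the post hoc parameter distributions
  (sd ≈ ln(p95/gm)/1.645 averaged with the lower tail). Q2/F, Q3/F and
  V3/F have degenerate reported distributions and carry no random
  effect.
- **Residual error σ_prop = 0.30, σ_add = 1 ng/mL**, and the albumin
  exponent 0.75 (chosen so the CL multiplier spans ≈ 0.87–1.13 over the
  observed albumin range 24–48 g/L).

Units are fixed throughout: mg doses, hours, ng/mL concentrations,
µg·h/mL AUC (note mg/(L/h) = mg·h/L ≡ µg·h/mL, so daily AUC = daily
dose / CL needs no conversion).

## MAP estimation and diagnostics

Individual random effects maximise the posterior with the population
model as prior; the objective is the standard −2 log-posterior with
combined proportional + additive residual variance. Observations below
the 5 ng/mL quantification limit are excluded from the objective (no
BLQ likelihood method is specified for the original analysis; exclusion
is common practice). Subjects with no quantifiable observations return
the prior mode with a flag.

Optimisation is L-BFGS-B from the prior mode plus four jittered starts
(fixed internal sub-seeds, so MAP estimates are a deterministic function
of the data), followed by a Nelder–Mead polish of the best solution.
Effects with zero prior variance are pinned at zero.

CWRES uses a first-order conditional linearisation around the MAP
estimate: marginal mean `f(η̂) − G η̂` and covariance `G Ω Gᵀ + diag(g)`
with `G` the finite-difference prediction gradient; the whitened
residual is obtained by Cholesky solve. Whether the original analysis
included an interaction term in `g` is unknown; this linearisation is an
approximation and is labelled as such.

The prediction-corrected VPC re-simulates the observed design (same
subjects, doses, times) with fresh random-effect and residual draws,
rescales observed and simulated values by the ratio of the bin-median
population prediction to the observation's population prediction, bins
by nominal protocol time point (sparse designs make time-binning
unstable), and pools replicates for the 2.5/50/97.5 percentile
envelopes. A single replicate therefore degenerates to that replicate's
percentiles.

## Exposure metrics

Daily AUC is (total mg dosed that day)/CL — for a linear model this is
the exact average daily steady-state contribution, and it is the form
derivable from "CL/F plus actual dosing history" without assumptions
about within-day timing. A profile-integration mode
(`simulate_concentrations` + trapezoid) exists for cross-validation and
agrees within 1% at steady state. Windows are 1-based closed day ranges;
the between-scans metric uses the half-open window (previous scan, last
scan] to avoid double counting; with a single qualifying scan the window
falls back to day 1 → scan and the result is flagged. Days with no dose
contribute zero.

## Exposure–response models

- **Static Cox:** maximum partial likelihood with Efron tie handling
  (ties at daily resolution are common). Wald CIs on the log scale.
- **Time-varying Cox:** daily exposure enters as a time-dependent
  covariate on counting-process (start, stop] intervals; consecutive
  equal-exposure days are merged into maximal constant spans first,
  which leaves the partial likelihood identical while shrinking the
  design matrix. A series shorter than follow-up is extended by
  last-value carry-forward with a warning. On a constant series the
  estimate equals the static fit to solver precision (tested).
- **Logistic models:** maximum likelihood, odds ratio per 1 µg·h/mL,
  Wald CI. Perfect or quasi-separation (small samples, e.g. the
  42-subject intracranial cohort) triggers a Firth-penalised fallback,
  flagged on the result.
- **Kaplan–Meier by quartile:** empirical quartiles; a value exactly on
  a boundary goes to the lower stratum (deterministic). Medians are the
  first time survival reaches 0.5 and are reported as not-reached when
  the curve never crosses it.
- **Stepwise covariate selection:** likelihood-ratio tests (better
  small-sample behaviour than Wald for add/drop decisions), forward
  entry at p < 0.05, backward elimination at p > 0.01, exposure never
  removable, ties broken by lowest p then alphabetically, failed
  candidate fits skipped and logged. The trace records every test.
- **Covariate–exposure forest:** per-covariate ordinary least squares on
  log AUC, so level-vs-reference ratios are geometric-mean ratios and
  percentile contrasts exponentiate `β·Δx`, each with a 90% Wald CI;
  missing covariate values are median/mode imputed with a warning.

## Virtual trial

The generator emulates the design, not any patient: covariates are
drawn from independent parametric approximations matched to the
reported summary statistics (truncated normals for age 57 (27–85),
albumin 41 (24–48) g/L, weight with a documented male/female shift,
log-normal laboratory values; categorical proportions as reported;
smoking prevalence 0.35 is a package choice, as it is not summarised).
Real covariate correlations beyond the weight–sex shift are not
reproduced. PK sampling follows the protocol windows, with the cycle-2
"6–8 h" sample fixed at 7 h nominal and the cycle 3–5 post-dose sample
drawn uniformly on 1–8 h.

Progression is simulated day by day from a baseline hazard (exponential
by default, median 730 days, optional Weibull shape) multiplied by
`exp(β·(AUC_d − 21.3))` with the current daily AUC; β defaults to
ln(1.03) per µg·h/mL and can be zeroed for null scenarios. Dose
reductions follow an exponential clock calibrated to a two-year median;
because longer survivors accumulate more reduction risk, a
reduction-plus-null-hazard configuration reproduces the static-metric
bias mechanism (static Cox drifts above HR 1 while the time-varying fit
stays centred on 1 — demonstrated in the operating-characteristic
suite). Response endpoints and adverse events are Bernoulli draws from
logistic truths: intracranial response anchored at probability 0.83 at
21.3 µg·h/mL with odds ratio 1.13; adverse-event endpoints anchored at
their reported marginal incidences (e.g. grade ≥2 amylase 19.5%, OR
1.06; grade ≥3 lipase 17.9%, OR 1.05) on the cycle-1 days 8–14 metric,
with onset uniform over treatment. All draws use per-subject,
per-purpose seeded streams, so cohorts are byte-identical under a fixed
seed and stable under subsetting.

Passing tests on this cohort establish internal validity — that the
estimators recover known truths under the stated design — not that the
generating assumptions (exponential hazards, independent covariates,
logistic AE mechanisms, protocol-exact adherence) hold in real
patients.

## Problem sizes and numerical choices

The operating-characteristic checks use 500 replicates for estimator
recovery and coverage (n = 42 and n = 123 per replicate), 300
replicates for the bias-mechanism demonstration, 200 replicates for VPC
self-consistency, and 10,000–20,000 draws for distributional checks on
the covariate generators; these sizes give Monte-Carlo standard errors
comfortably below the assertion tolerances. Optimiser tolerances are
1e-12 (ftol) / 1e-8 (gtol) for MAP; the simulator's analytic and ODE
routes agree to 1e-5 relative and the analytic route satisfies mass
balance (AUC₀₋∞ = dose/CL) to numerical integration accuracy.

## Known limitations

- One finite-sample caveat surfaced by the recovery suite: at n = 42
  with ~17% non-responders, the arithmetic mean of the estimated odds
  ratio across replicates sits ≈ 0.03–0.05 above the generating 1.13 —
  ordinary maximum-likelihood small-sample bias amplified by the
  convexity of exp(β̂), not an implementation artefact (the median is
  much closer and CI coverage is nominal).
- No BLQ likelihood contribution; no allometric scaling or time-varying
  clearance; no Cmax/Cmin metrics; the comparator arm is accepted only
  as an externally supplied survival curve for plotting, never
  modelled.
- The end-of-treatment anchor for AE exposure averaging is the last
  dose day (the 30-day AE window is used only for endpoint capture);
  whether the source analysis extended averaging into follow-up is
  unspecified.
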