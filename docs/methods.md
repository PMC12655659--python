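# Methods

`radpk` implements the population pharmacokinetic model of radotinib, a
second-generation BCR-ABL1 tyrosine-kinase inhibitor used in chronic-phase
chronic myeloid leukemia (CML-CP), together with the machinery needed to
estimate, diagnose and exercise that model: FOCE-I estimation, stepwise
covariate modelling, visual predictive checks, a nonparametric bootstrap and
Monte Carlo dosing-regimen simulation.

## Structural model

Drug amounts (mg) move through an absorption depot, a central and a
peripheral compartment:

    dA_a/dt = sum_d r_d(t) - ka * A_a
    dA_c/dt = ka * A_a - [CL * g(t) / Vc + Q / Vc] * A_c + (Q / Vp) * A_p
    dA_p/dt = (Q / Vc) * A_c - (Q / Vp) * A_p

Oral input is the analytic transit-chain function for a dose D given at
t_d:

    r_d(t) = F * D * ktr * (ktr * (t - t_d))^N * exp(-ktr * (t - t_d)) / Gamma(N + 1)

with ktr = (N + 1) / MTT, the parameterization in terms of the mean transit
time MTT and a continuous number of transit compartments N (the chain counts
the step feeding the depot).  Elimination is first order with a circadian
cosine modulation applied to clearance only:

    g(t) = 1 + a * cos(2 * pi * (t - t_peak) / 24),     |a| < 1

Apparent (…/F) parameters are used throughout; F is fixed at 1 and the only
unit conversion (mg/L to ng/mL, factor 1000) happens at concentration
output.

Covariate model: clearance carries a proportional disease effect,
CL = CL_pop * (1 + theta_dis * (1 - CML)), so healthy volunteers clear the
drug faster than CML-CP patients; the central volume carries a linear age
effect centred at 31 years, Vc = Vc_pop * (1 + theta_age * (AGE - 31)) with
a negative slope.  The linear age model has finite support; ages that drive
Vc non-positive raise a domain error.

Default parameter values (the packaged profile
`radpk/profiles/final_model.yaml`) are the published final-model estimates:
CL_pop 23.0 L/h, theta_dis 0.646, circadian amplitude 0.683 with acrophase
at 7 h after first dose, Vc_pop 383 L, theta_age -0.0129/year, Q 132 L/h,
Vp 519 L, ka 1.59 1/h, MTT 1.88 h, N 6.58.

## Random effects and residual error

Log-normal interindividual variability (eta SDs: CL 0.389 estimated, MTT
0.316 and N 0.447 fixed — the squares reproduce the fixed variances 0.1 and
0.2), one interoccasion eta (SD 0.698) shared by Vc and Vp per
subject-occasion, and proportional residual error y = f * (1 + eps) with
eps ~ N(0, 0.2^2).  Negative simulated concentrations are truncated at zero
with a warning; no eta-eta correlations are modelled.

## Numerics

* Workhorse integrator: fixed-step classical RK4 compiled with numba
  (`radpk._ode`), step 0.05 h for simulation/generation and 0.1 h inside
  estimation.  The transit forcing is smooth (each dose's input rate starts
  at zero for N > 0), so dose events introduce no discontinuities; the
  fastest model time scale is 1/ktr ~ 0.25 h and the fixed step resolves the
  solution to ~1e-4 relative, verified against `scipy.integrate.solve_ivp`
  at rtol 1e-8, which remains available as the adaptive reference path of
  `simulate_profile`.
* Steady state: occasion-2 (Day-14) concentrations and the fast Monte Carlo
  path evaluate the exact periodic steady state of the repeating regimen via
  the monodromy (fundamental) matrix of the 24 h-periodic linear system:
  integrate one period with the three homogeneous unit solutions, solve
  (I - Phi) x* = b, and superpose.  The brute-force 14-day burn-in
  (`steady_state_window`, with a trough-convergence check) is retained and
  agrees with the periodic solution to < 0.1%; after 312 h about 11 terminal
  half-lives have elapsed, so treating Day 14 as fully at steady state is
  exact to < 0.1%.
* Exposure metrics: trapezoidal AUC on a 0.25 h window grid; Cmax/tmax from
  the grid maximum; Ctrough is the concentration at the end of the 24 h
  window, immediately before the next window-opening dose (for twice-daily
  regimens the mid-window pre-dose concentration is not averaged in).
* Dose-clock alignment: doses are placed at TIME = 0 (mod 24) for once-daily
  and TIME = 0 and 12 for twice-daily regimens, with the circadian acrophase
  at TIME = 7 — i.e. the simulation clock equals the model's TIME-since-
  first-dose clock.  Because the source analysis never states where doses
  sit relative to the circadian phase, this is the largest free choice in
  the exposure simulations; `--dose-clock-offset` (and the `clock_offset`
  argument) shifts the circadian clock for sensitivity analysis, and the
  acceptance suite sweeps it over 0-21 h.  Steady-state exposure medians for
  once-daily regimens move by up to ~18% across that sweep; twice-daily AUC
  is nearly alignment-invariant because its forcing is 12 h-periodic.

## Estimation (FOCE-I)

Per subject, the empirical Bayes eta maximizes the joint density of the
observations and the eta prior (proportional-error variance evaluated at the
individual prediction).  The marginal -2 log-likelihood is approximated by
the standard first-order-conditional expression

    OFV_i = ln det V_i + r_i' V_i^{-1} r_i,
    V_i = F_i Omega F_i' + diag(sigma^2 f_i(eta_hat)^2),
    r_i = y_i - f_i(eta_hat) + F_i eta_hat,

with F_i = df/deta by central differences and the n ln(2 pi) constant
omitted.  CWRES are the Cholesky-whitened residuals L^{-1} r_i.  Agreement
of this approximation with the exact marginal likelihood is verified against
adaptive quadrature on one-eta toy models (within 2% OFV).  The outer
problem runs Nelder-Mead on log-transformed positive parameters (signed
covariate coefficients stay on the natural scale); standard errors come from
the finite-difference Hessian of the OFV (cov = 2 H^{-1}).  Inner solvers:
bounded Brent for one eta, BFGS for several; inner iterates beyond six prior
SDs hit a soft barrier to keep line searches finite, and predictions are
floored at 1e-10 ng/mL inside the error variance.

Below-quantification handling is M1 (discard, the default policy at the
5 ng/mL limit) or fixing at half the limit; likelihood-based BLQ methods are
out of scope.

## Stepwise covariate modelling

Greedy best-first forward addition (largest OFV drop first, threshold 3.84,
chi-square 1 df at p < 0.05) followed by backward elimination (retention
requires an OFV rise > 6.63, p < 0.01).  Continuous covariates use linear,
power or exponential forms centred at the dataset median; categorical
covariates use proportional or additive forms.  Candidates collinear
(|r| > 0.9) with an already-included covariate are skipped with a log entry,
and candidate fit failures are skipped rather than fatal.

## Synthetic data generator

The generator reproduces the two-cohort design that produced the modelling
dataset: 23 healthy volunteers (single 400 mg dose; samples pre-dose and
0.5-48 h) and 24 CML-CP patients (300 mg every 12 h; samples pre-dose and
1-12 h post-dose on Days 1 and 14).  Covariates are drawn to match the
published demographics: volunteers all male with ages uniform over 20-51;
patients 54% male with ages from a log-normal (median 32, log-SD 0.28)
truncated to 21-72 — the published table gives only median and range, so the
shape is an emulation choice, calibrated so the virtual-population median
age lands within +/-1 year of 32.  Weights, heights and laboratory values
are truncated normals/log-normals inside the published ranges; they carry no
effect in the final model and exist as covariate-modelling candidates.
Volunteers are a single-occasion cohort; patients draw independent IOV etas
for Days 1 and 14.  Day-1 pre-dose samples are true zeros flagged below the
quantification limit.  What the generator does **not** emulate: real-data
missingness/dropout patterns (available separately as
`dropout_and_missingness`), assay error structure beyond the proportional
model, concomitant-medication effects, and any ethnicity or sex effects —
so passing recovery tests demonstrate internal consistency of the model and
estimator, not robustness to the misspecifications real data would add.

## Validation experiments (design choices)

* Parameter recovery: 10 replicate synthetic studies generated with IIV on
  CL only (omega_MTT = omega_N = omega_IOV = 0) and fitted from
  20%-perturbed initials with cl_pop, the disease coefficient, omega_CL and
  sigma free and the remaining structural parameters fixed at their
  generating values.  This isolates the quantities the experiment is about
  (the disease contrast and its variability) and keeps each fit's inner
  problem one-dimensional; tolerances are 15% median bias for the fixed
  effects and 25% for omega_CL.
* SCM power/type-I: five replicates each with and without the simulated
  disease effect, three candidates (disease on CL, weight on CL, age on Vc),
  cl_pop plus candidate coefficients free and the variance components fixed
  at truth — the experiment probes the selection thresholds, not variance
  estimation.  Data for these runs are generated without the age effect so
  the disease contrast is the only covariate signal.
* CWRES calibration and VPC coverage are checked on data self-simulated
  under the full published variability.

Problem sizes used by the shipped experiments (10 recovery fits, 5 + 5 SCM
replicates, 200-replicate VPC, 2400-patient exposure simulations) were
chosen to keep the whole suite at desk scale while leaving the statistical
assertions well-powered.

## Known limitations

* The printed steady-state exposure table that the Monte Carlo module
  targets sits 10-14% above what the printed final model can produce for
  twice-daily dosing at *any* dose-clock alignment (at periodic steady state
  AUC_0-24 = daily dose / effective clearance, and the concentration-weighted
  circadian factor stays within ~2% of 1 for symmetric 12 h dosing, so the
  twice-daily AUC is pinned near daily dose / CL_pop).  The corresponding
  acceptance checks are left failing rather than recalibrated; the package
  reports what the model yields.  The published observed (non-compartmental)
  exposure is in fact closer to this package's simulations than to the
  printed simulated table.
* NONMEM's exact objective-function constants and boundary handling are not
  reproducible from the publication; this package's conventions (constant
  omitted, conventions above) are validated against quadrature oracles
  instead of NONMEM outputs, and the real-data OFV is not a target.
* No saturable elimination, lag-time or zero-order absorption variants, no
  covariance blocks between etas, no M3 BLQ likelihood, no infusion records
  or multi-analyte support.
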