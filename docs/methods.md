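# Methods

## Structural model

Remimazolam disposition is described by a linear mammillary
three-compartment model with elimination from the central compartment:

    dA1/dt = -(k10 + k12 + k13) A1 + k21 A2 + k31 A3 + u(t)
    dA2/dt =  k12 A1 - k21 A2
    dA3/dt =  k13 A1 - k31 A3

parameterised by clearances and volumes (`k10 = CL/V1`, `k12 = Q2/V1`,
`k21 = Q2/V2`, `k13 = Q3/V1`, `k31 = Q3/V3`).  Central (arterial) plasma
is the observation compartment, `C = A1/V1`; there is no arterio-venous
submodel and no saturable elimination.  Dosing input `u(t)` is a
superposition of zero-order infusions; an intravenous "bolus over 1 min"
is represented as a 1-min infusion, never as an instantaneous dose.

Internal units are min, mg, L (so mg/L for concentration); the interface
reports ng/mL and ng·h/mL (1 mg/L = 1000 ng/mL).  Conversions are
centralised in `remipk.units`.

### Exact solution

Within any interval of constant total infusion rate the system is
`A' = K A + u` with constant `u`, solved exactly by

    A(t0 + tau) = e^{K tau} A0 + K^{-1} (e^{K tau} - I) u.

The mammillary rate matrix is similar to a symmetric matrix under the
diagonal scaling `D = diag(1, sqrt(k21/k12), sqrt(k31/k13))`, so its
eigenvalues are real and negative and the solver uses `eigh` on the
symmetrised matrix — numerically robust including (near-)repeated
eigenvalues.  When an intercompartmental clearance is exactly zero the
scaling degenerates and the solver falls back to an augmented-matrix
exponential per segment, which needs no invertibility assumptions.
Output grids are augmented with event-boundary times so infusion-end
peaks are never truncated by grid resolution.  Solver error against an
adaptive ODE oracle is below 1e-6 relative (typically ~1e-9); mass
balance `CL x AUC = dose` holds to 1e-9.

`AUC0-inf` is computed analytically as total dose / CL — exact for any
schedule under linear kinetics — and cross-checked against trapezoidal
integration plus a terminal-slope tail in the tests.

## Parameters and variability

Typical adult values at the 63-kg reference weight (`remipk.params`):
CL 1.03 L/min, V1 2.08 L, V2 10.9 L, Q2 1.49 L/min, V3 19.7 L,
Q3 0.266 L/min.  Body weight enters through fixed-exponent allometry
(0.75 for CL/Q2/Q3, 1.0 for V1/V2/V3).

Inter-individual variability is log-normal on all six parameters,
`P_i = P_TV exp(eta_i)`, with variances
w2 = (0.0203, 0.00546, 0.0509, 0.107, 0.072, 0.0777) for
(CL, V1, V2, Q2, V3, Q3) and covariances 0.00948 between (CL, V1) and
0.0555 between (V2, Q2); both 2x2 blocks are verified positive definite
at assembly.  Note the variability list includes Q2: the reported
variance table is taken as authoritative for which parameters carry
random effects.

Residual error is additive on **log** concentration with variance
0.0162 (~12.7% CV).  An additive error of that magnitude on the natural
ng/mL scale would be physically negligible against peak concentrations in
the thousands of ng/mL, while on the log scale it matches the observed
proportional assay noise; the scale is nevertheless a switch in
`ResidualSpec` for sensitivity analysis.  Simulated exposure metrics are
computed on *true* (noise-free) concentrations; residual noise is only
added when emulating assayed datasets.

### CES1 ontogeny

Remimazolam is inactivated by carboxylesterase 1.  Hepatic CES1 abundance
matures as a Hill function of age: 20% of adult abundance at birth,
half-maturation at 1.10 years, Hill coefficient 0.56.  `fces1` implements
this curve and `fces1_clearance_factor` exposes it as a clearance
multiplier normalised to a 30-year-old reference adult.  It is **off by
default**: the adult-derived model covers ages where CES1 is essentially
mature (>= 3 y the factor is within ~10% of adult), and the ontogeny term
was evaluated but not retained in the final adult model.  The published
form of the ontogeny equation is typographically mangled; the Hill
reading adopted here is the one consistent with its printed constants
(birth fraction 0.2, half-maturation age 1.10 y, exponent 0.56) and with
the cited proteomic ontogeny literature.

### Derived covariates

BSA is not specified by the source workflow; the Du Bois formula
(0.007184 W^0.425 H^0.725) is used and isolated behind one function so it
can be swapped.  eGFR follows the BSA-adjusted MDRD equation with
creatinine in umol/L.  These feed the covariate-screening machinery only;
no covariate beyond weight is in the final model.

## Virtual populations

* Adults: weight ~ Normal(63.4, 7.3) kg truncated at +/-3 SD (to exclude
  non-physiological draws; the source is silent on truncation), age
  uniform 18-51 y, ~20% female.  Age and sex do not enter the model.
* Pediatric weight bands: weight uniform on the band.  The original
  virtual-demographics table is not available; a uniform band is the
  least-informative choice and puts the band median at the midpoint
  (20 kg for 10-30 kg, 50 kg for 30-70 kg), which reproduces the
  published band exposures closely — the 30-70 kg band is the most
  sensitive to this convention (its published median AUC sits ~4% below
  the uniform-band value).
* Seven age cohorts (<1 through >18 y) carry the published median weights
  6.6-57.0 kg for cohort-level simulations.

Monte-Carlo simulation draws one eta vector per subject, scales typical
values allometrically, and evaluates the exact solution on a grid with
1-s resolution over the first 5 min (the induction peak), 0.5-min to 4 h,
and 5-min thereafter.

## Exposure metrics and dose recommendation

Cmax is the grid maximum (with event boundaries injected), C2h is the
concentration at the end of the 2-h maintenance segment (log-linear
interpolation), and AUC0-inf is analytic.  Maintenance starts at the end
of the 1-min induction by default ("followed by"); the
loading+maintenance study generator uses a concurrent start per that
study's design.  The difference at the 2-h readout is negligible but the
policy is explicit and switchable.  The 2-h readout is taken at the end
of the maintenance segment (121 min under the default policy).

Population summaries report medians with empirical 5th/95th percentiles
(type-7).  This "90% interval" is a prediction interval of individual
exposures — what the exposure-band figures actually depict — not a
confidence interval on the median.  The adult target window per metric is
[5th percentile of the 1.0 mg/kg/h regimen, 95th percentile of the
3.0 mg/kg/h regimen].

A candidate pediatric regimen *passes* when all three metric medians fall
inside the window — the weakest criterion consistent with "comparable to
the adult exposure range"; no formal accept/reject rule is stated in the
source workflow, so this choice is explicit in `remipk.dosing`.  The
band's required maintenance *ceiling* is the smallest candidate rate (at
the 0.3 mg/kg reference induction) whose median C2h and AUC reach the
5th percentiles of the adult high-maintenance regimen, i.e. the regimen
enters the upper target region; Cmax is excluded from the ceiling rule
because both adult reference regimens share the induction dose, so the
peak is governed by induction, not maintenance.  A 0.2 mg/kg induction is
carried as a deliberately conservative option: its verdict waives the
Cmax lower bound and is flagged as policy-based rather than
exposure-matched.  With candidate rates {1, 2, 3, 4} mg/kg/h this
reproduces the weight-band stratification: 30-70 kg keeps the adult
ceiling 3.0 mg/kg/h, 10-30 kg requires 4.0 mg/kg/h.

## Estimation layer

The estimator maximises an approximate marginal likelihood.  Per subject,
the random-effect vector is profiled to its empirical-Bayes mode by
damped Gauss-Newton on the conditional posterior; the subject's -2 log
marginal likelihood is then the Laplace approximation with the
Gauss-Newton Hessian `J'J/sigma2 + Omega^{-1}` (a FOCE-family objective).
Fixed effects, random-effect variances and the residual variance are
log-parameterised (guaranteeing positivity) and minimised with L-BFGS-B;
empirical-Bayes modes are warm-started between outer iterations.  The
fitted Omega is diagonal.  Exact reference-implementation conditional
estimation is out of scope: only OFV *differences* are used anywhere
(model selection thresholds 3.84 / 10.83), never absolute OFV values,
which are approximation-dependent.

Numerical choices: residual likelihood on log-concentration (predictions
floored at 1e-9 ng/mL before logs); inner Newton tolerance 1e-7 on the
gradient with Levenberg damping and step-halving line search; outer
finite-difference step 1e-4 on log-parameters; non-finite predictions
return a large penalty rather than crashing the optimiser.  A compiled
(numba) kernel evaluates stacked parameter vectors — the finite-difference
Jacobian in one call — and is verified against the public solver in the
tests; without numba a vectorised numpy path computes the identical
quantity.

On pooled synthetic realisations of the two study designs (~204 subjects)
the fit recovers CL within ~1%, the other fixed effects within ~5%, and
w2(CL) within ~25%.  Random-effect variances shrink somewhat under the
diagonal-Laplace approximation (the generator uses correlated blocks that
the fit omits), which is the known direction of bias for this objective;
the acceptance tolerance (30% on w2(CL)) reflects it.

### Diagnostics

* **Covariate screening**: Pearson correlation of subject-level
  covariates with empirical-Bayes etas; eligibility at |R| >= 0.3;
  within collinear groups (|R| > 0.8) only the strongest representative
  is kept.  Screening against etas (rather than raw concentrations) is
  the standard practice adopted here.
* **Stepwise selection**: greedy forward inclusion (largest OFV drop
  > 3.84), then backward elimination (retain only effects whose removal
  raises OFV > 10.83).  `refit="full"` re-optimises everything per
  candidate; the default `"coef-only"` profiles only the covariate
  coefficients with the structural/variance parameters held at the base
  estimates — a score-test-flavoured variant with the same asymptotic
  null behaviour at a fraction of the cost.  Its type-I calibration
  (~5% per null candidate at the 3.84 threshold) is verified over 200
  simulated replicates of a compact four-arm design with IIV on CL only;
  this scaled-down configuration keeps the calibration experiment at
  desk scale.
* **Bootstrap**: subjects resampled with replacement, each replicate
  refitted from the original optimum; medians and 2.5/97.5 percentiles
  reported; failed replicates counted and excluded, aborting if more than
  half fail.
* **pcVPC**: observations and simulated replicates are normalised by
  (bin-median typical prediction / record's typical prediction), binned
  by time quantiles (degenerate bins merged), and the observed 5/50/95th
  percentiles are compared with 95% intervals of the same statistics over
  the simulated replicates.

## Synthetic studies

`design_ia` encodes a single-ascending-dose study: eleven 1-min IV arms
at 0.007-0.32 mg/kg with group sizes (3,3,3,6,6,6,6,6,6,9,9) and 19
sampling times (pre-dose, 1-45 min, 1-8 h).  `design_ib` encodes a
loading+maintenance study: 0.29 mg/kg over 1 min given concurrently with
1.08 mg/kg/h for 2 h, 26 sampling times through 4 h after infusion end,
8 subjects.  Demographics: weight Normal(62.8, 7.3) kg truncated to
[50.2, 83.8], age uniform 18-51 y, ~20% female.  Samples below the
0.5 ng/mL LLOQ are excluded (the simplest below-quantification policy;
no other handling is specified) with the exclusion count reported.  The
crossover/antagonist structure of the second study is collapsed to a
single period: the antagonist affects pharmacodynamics, not this PK
model.

What the generator does **not** emulate: arterio-venous concentration
differences, assay error structure beyond the residual model, real
demographic covariance (age-height-weight growth curves), dropout or
sampling-time deviations.  Passing recovery tests therefore demonstrates
internal statistical consistency of the estimation machinery, not
performance on real clinical data.

## Problem sizes and determinism

Monte-Carlo acceptance targets use n = 1000 subjects per scenario;
parameter recovery uses ~204 subjects pooled from both designs; the
selection-calibration experiment uses 200 replicates of 20 subjects; the
pcVPC check uses 400 simulated replicates of the 63-subject design.
Every stochastic routine takes an explicit seed and is bit-reproducible
under it.

## Known limitations

* The estimation objective is a Laplace/FOCE approximation with a
  diagonal fitted Omega; absolute OFV values are not comparable to other
  software and variance components shrink a few tens of percent on sparse
  designs.
* Standard errors come from an optional finite-difference Hessian
  (`PopPKResults.compute_se`), not a full covariance step.
* The pediatric weight-band distribution is a modelling convention
  (uniform), not observed demographics.
* No pharmacodynamics, no exposure-response: the recommendation matches
  exposure only, inheriting the assumption that equal exposure implies
  comparable effect across ages.
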