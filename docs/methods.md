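# Methods

`appwt` models the link between patient-reported appetite and body
weight in non-small-cell lung cancer (NSCLC), and uses that link to
define clinically meaningful appetite-loss thresholds. This note
documents the model, the estimation machinery, the synthetic study
conditions, the numerical choices, and the known limitations.

## The structural model

Appetite is the LCSS appetite item: a 0–100 mm visual-analogue score
where higher values mean worse appetite. One subject's trajectory is

    L(t) = L0 + (e^{SLP·t} − 1) − PMAX·(1 − e^{−Kp·t})

with `L0` the baseline score (mm), `SLP` the appetite-loss rate (1/day)
carrying disease progression and treatment toxicity, and `PMAX` (mm) /
`Kp` (1/day) an asymptotic-exponential improvement term carrying
recovery, supportive care and placebo response. `SLP` is constrained
non-negative: loss and improvement are carried by separate terms rather
than by the sign of one rate.

Body weight follows an indirect-response (turnover) model in which the
appetite score inhibits the zero-order weight input:

    dWT/dt = Kin·(1 − Imax·L(t)/(IC50 + L(t))) − Kout·WT

`Kin` (kg/day) is the constant weight input, `Imax` ∈ [0, 1] the maximal
inhibition, `IC50` (mm) the score of half-maximal inhibition, and `Kout`
is tied to the baseline steady state,

    Kout = Kin·(1 − Imax·L0/(IC50 + L0)) / WT0,

so that weight is constant whenever appetite does not change. The
turnover creates a physiological lag between appetite change and weight
change, which appears as a hysteresis loop in appetite-versus-weight
phase plots.

Two conventions the instrument forces on us:

* `L(t)` is analytically unbounded (the loss exponential grows without
  limit); the inhibition term receives the score **clamped to
  [0, 100] mm**. Scores beyond the scale have no meaning for the
  instrument, and the clamped trajectory is also what observations are
  generated from. This is a design decision, documented rather than
  inferred.
* Observed scores at 0 or 100 mm can be treated as censored: their
  likelihood contribution is the Gaussian probability of exceeding the
  bound (on by default, configurable off).

## Numerical treatment of the weight ODE

Given `L(t)` the turnover ODE is linear, so two solution paths exist:

* `weight_trajectory(..., method="ivp")` — adaptive integration
  (LSODA, rtol 1e-10, atol 1e-12). This is the reference path; at these
  tolerances it agrees with a high-resolution quadrature of the
  integrating-factor solution to better than 1e-6 kg over 1000 days.
* `method="exact"` — an exact exponential-integrator recursion on a
  refined grid with the input interpolated linearly between nodes
  (error O(h²); ~3e-8 kg at half-day steps). Accumulation is segmented
  so `e^{Kout·t}` cannot overflow on long horizons. This path is ~100×
  faster and is what the fitting and simulation layers use, at 1-day
  (fitting) or 2-day (refinement, virtual studies) steps — integrator
  error is then orders of magnitude below the 1.5% proportional
  residual noise.

## Population model and estimation

Parameters are log-normal (`SLP`, `Kp`, `Kin`, `IC50`, `WT0`) or
scaled-logit-normal (`L0` and `PMAX` on (0, 100) mm, `Imax` on (0, 1))
across subjects. By default `L0`, `SLP`, `PMAX`, `WT0` and `Imax` carry
between-subject variability (`omega`, SDs on the transformed scales);
`Kp`, `Kin` and `IC50` are population constants. ECOG performance
status shifts the logit of baseline appetite additively per level
(higher ECOG → worse appetite); female sex multiplies baseline weight
by `1 − beta_sex` (the two cohorts' reductions are 18.8% and 11.3%).
Residual error is additive (mm) on the clamped appetite prediction and
proportional on weight — the conventional choices for a bounded
visual-analogue score and for body weight.

Estimation proceeds in three stages:

1. **Warm start** — a naive-pooled fit of the typical values (no
   deviations) against all data.
2. **MAP-EM** — per-subject empirical-Bayes modes by a batched damped
   Newton iteration (all subjects updated simultaneously on shared,
   padded time grids; finite-difference derivatives double as the
   Laplace curvature), alternating with closed-form updates: means and
   covariate coefficients by least squares on the modes, omegas as the
   mean of squared modes **plus** the Laplace conditional variances
   (a mode-only update collapses omega), residual SDs from pooled
   residuals, and the shared typical values by a quasi-Newton profile
   pass over the data likelihood.
3. **Monte-Carlo marginal refinement (MCML)** — the random effects are
   integrated out by importance sampling with a fixed set of draws from
   the Laplace proposal N(mode, 1.2²·Σ). Because the draws are fixed,
   the simulated marginal log-likelihood is a smooth deterministic
   function of all population parameters and is maximized by a
   preconditioned L-BFGS (coordinates rescaled by inverse root
   curvature). The refinement removes the sigma/omega shrinkage bias of
   mode approximations and supplies the curvature information — the lag
   between appetite change and weight change — that identifies the
   turnover parameters, which fixed-mode coordinate ascent cannot feel.

The trajectory decomposition makes the likelihood multimodal in `Kp`:
a fast-but-small improvement can mimic a slow-but-large one on sparse
visit schedules. The whole pipeline therefore runs from three `Kp`
starting values (0.012, 0.04, 0.12 /day) and the basins are compared on
the simulated marginal, each under its own fresh proposal (comparing
basins under a stale proposal is biased against distant candidates and
was verified to mis-rank them).

The reported `loglik` is the final simulated marginal. The EM trace is
**not** monotone: the Laplace-corrected omega update and the basin
selection are not ascent steps on a single fixed surface. The invariant
the implementation does guarantee — and the suite tests — is that the
returned state attains the best simulated marginal among those visited.

Standard errors are diagonal observed-information estimates from
central second differences of the simulated marginal (smooth in the
fixed draws); cross terms are neglected. They feed the virtual-study
stage as the spread of the typical values, which is their only
downstream use.

### Identifiability at the trial designs

The chemotherapy-profile schedule (appetite at baseline, cycles 2 and
4, end of treatment) leaves roughly two informative post-baseline
appetite points per subject once scores saturate, so:

* `(PMAX, Kp)` is weakly identified even with the appetite→weight link
  fixed (validation mode): errors of 25–45% on these two persist at
  n = 380 while `L0`, `SLP` and `WT0` recover to 1–3%.
* `(Kin, Imax, IC50)` is identified through the turnover lag and the
  inhibition curvature over the observed score range; at n = 300 the
  recovery errors scatter at roughly the 10–20% (`Kin`, `Imax`) to
  20–70% (`IC50`) level across seeds — an information limit of the
  design, not an estimator defect (the same estimator recovers all
  parameters to ≤1% on a dense noiseless design).

This is why validation mode fixes `Kin`, `Imax` and `IC50` when
moving to the chemotherapy cohort and re-estimates only the trajectory
and baseline weight.

## Synthetic study conditions

The generator emulates the two trial arms behind the analysis; real
trial data are licensed and not redistributable, so every downstream
stage is exercised on virtual cohorts.

* **Recovering profile** (post-chemoradiotherapy supportive care):
  typical `L0` 25 mm, `SLP` 2e-3/day, `PMAX` 16 mm, `Kp` 0.03/day,
  `WT0` 74 kg — early appetite improvement, weight gain, late decline.
  Appetite visits at weeks 0/2/5/8 then 6-weekly; weekly weights for 8
  weeks then 6-weekly.
* **Chemotherapy profile** (3-weekly docetaxel): typical `L0` 40 mm,
  `SLP` 0.038/day, `PMAX` 12 mm, `Kp` 0.02/day, `WT0` 71 kg — net
  persistent appetite loss (median predicted loss ≈ 9 mm at 3 months)
  and weight loss (median ≈ −0.2 kg by day 90, ~−3.5 kg by ~6 months).
  Appetite at baseline, cycles 2/4 and end of treatment (day 168);
  weight every cycle. The loss rate is set high enough that the net
  trajectory declines despite a realistic improvement amplitude; an
  improvement term much smaller than the 6-mm residual SD would be
  unidentifiable by construction.
* Shared link: `Kin` 0.9 kg/day, `Imax` 0.35, `IC50` 40 mm. Between-
  subject SDs 0.35/0.40/0.50/0.18/0.40 for `L0`/`SLP`/`PMAX`/`WT0`/
  `Imax` on transformed scales. Residual SDs 6 mm and 1.5%.
* **Covariates** sampled at the trial arms' frequencies (sex, ECOG
  0–2, smoking status, age).
* **Survival**: Weibull proportional hazards (shape 1.5) on the
  standardized transformed `SLP` (+0.35 per SD, worse) and `PMAX`
  (−0.25 per SD, protective), current/former smoking and ECOG level.
  Baseline scales are calibrated so the *marginal* median OS matches
  the arms (≈21 and ≈11.7 months); administrative censoring at 2000 /
  1100 days. The functional form is the package's own choice; only the
  directionality is anchored.
* **Dropout** is terminal: observation stops 30 days before death
  (never before baseline), so the VPC's dropout correction has a real
  mechanism to correct for. Fewer than 5% of subjects fail the
  two-observations-per-endpoint inclusion rule under these conditions.

All randomness flows through seeded `numpy` PCG64 generators; cohorts
are bit-reproducible.

What the generator does **not** emulate: visit-level missingness
unrelated to death, measurement error in covariates, non-proportional
hazards, informative censoring other than the terminal mechanism, and
any real-data idiosyncrasies of the LCSS instrument (digit preference,
anchoring). Passing tests demonstrate internal consistency of the
machinery under the stated mechanisms, not validity on real trial data.

## Diagnostics

Goodness of fit reports observation/individual-prediction pairs per
endpoint with the slope and intercept of their regression. The VPC
simulates replicate cohorts from the population estimates using every
subject's planned design and covariates **and the dropout process**
(simulation-based correction), bins observations into 8 quantile-based
time bins, and compares observed 10th/50th/90th percentiles with the
5th–95th percentile band of the same statistics across replicates.
Weight is assessed as change from baseline. One calibration caveat: a
perfectly specified model leaves the observed median outside a 90%
band in ~10% of bins by construction, so "all bins inside" is the
typical but not the guaranteed outcome of a correct model.

## Virtual studies and the 3.5-kg equivalence

Each replicate study draws population typical values from Gaussian
perturbations on the transformed scale (SD = standard error), then
simulates noise-free individual trajectories for a bootstrap sample of
covariates; within-replicate randomness is shared across replicates
(common random numbers), so the replicate spread isolates parameter
uncertainty. Per replicate the median appetite-change and
weight-change curves are stored on a 2-day grid.

The appetite equivalent of a 3.5-kg weight change (5% of a 70-kg
adult, the usual cachexia-trial threshold) is read at the **earliest
crossing time** of the weight target (linear interpolation between
grid nodes), from the same replicate's appetite curve. The hysteresis
loop makes "appetite change per weight change" time-dependent; the
crossing-time convention resolves that ambiguity explicitly.
Replicates that never reach the target are excluded and counted; more
than 50% missing flags the result as not reached. The 90% CI is the
5th–95th percentile across replicates.

## Survival layer

Model parameters enter Cox models as standardized transformed
empirical-Bayes estimates (hazard ratios per SD; the scaling in the
source figures is unstated, so it is made explicit here). Ties use the
Efron approximation (lifelines). Clinical covariates are selected by
an L1-penalized Cox path (scikit-survival coxnet) with 5-fold
cross-validated Verweij–van Houwelingen deviance and the
one-standard-error rule.

The cutoff scan classifies subjects by model-predicted appetite loss
(score increase, mm) or weight loss (kg) at a landmark (30 or 90
days), fits one Cox model per cutoff (0–15 mm by 1 mm; 0–5 kg by
0.5 kg) adjusted for the selected covariates, and selects the lowest
cutoff with p < 0.05 and HR > 1 — applied literally, with no
multiplicity correction (an optional permutation-adjusted p is
computed on request, off by default to match the rule). Two guards the
rule itself does not state: only subjects surviving beyond the
landmark are analysed (no immortal time), and cutoffs leaving fewer
than five subjects on either side are skipped. Under a null hazard
the naive rule selects *some* cutoff in roughly 10–14% of scans — the
familywise cost of ~12 correlated tests at α = 0.05 — which is worth
knowing before interpreting a single selected threshold.

## Problem sizes used in the checks

The self-checks run at desk scale, chosen to finish on one CPU while
leaving the conclusions stable: recovery fits at n = 300 (full) and
n = 200 (validation mode), VPC self-consistency at n = 200 with 500
replicates, cutoff-scan operating characteristics at n = 400 × 50
replicates, and the end-to-end reproduction script at n = 150 per
cohort with 200 virtual studies. The acceptance script scales linearly
in subjects and replicates if larger runs are wanted.

## Known limitations

* The estimator is simulation-based; estimates carry O(1/M) importance-
  sampling bias (M = 200 draws by default) on top of the finite-sample
  scatter. Doubling M changes chemotherapy-fit typical values by ~1-3%.
* `(PMAX, Kp)` and `IC50` are weakly identified at the sparse
  chemotherapy design (see above); their estimates should be read as
  ridge coordinates, not precise values.
* Between-occasion variability, time-varying covariates, competing
  risks and proportional-hazards diagnostics beyond Schoenfeld-style
  export are out of scope.
* The survival generator's Weibull-PH form and the terminal-dropout
  mechanism are the package's own modelling choices; alternatives can
  be swapped behind `SurvivalGeneratorSpec`.
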