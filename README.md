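# appwt

Population modelling of patient-reported appetite, body-weight turnover
and survival thresholds in non-small-cell lung cancer (NSCLC).

## The problem

Appetite loss affects most lung-cancer patients, drives unintended
weight loss and cachexia, and is associated with shorter survival — yet
it has no standard quantitative endpoint. `appwt` implements a
mechanism-based population analysis that turns the patient-reported
LCSS appetite item (a 0–100 mm visual-analogue score; higher = worse
appetite) into such an endpoint, for biostatisticians and
pharmacometricians working with longitudinal patient-reported outcomes
and survival data.

The core model couples an appetite trajectory

    L(t) = L0 + (e^{SLP·t} − 1) − PMAX·(1 − e^{−Kp·t})

(`SLP`: appetite-loss rate; `PMAX`, `Kp`: extent and onset rate of
recovery/placebo improvement) to a body-weight indirect-response
(turnover) model in which the score inhibits weight input:

    dWT/dt = Kin·(1 − Imax·L(t)/(IC50 + L(t))) − Kout·WT,
    Kout   = Kin·(1 − Imax·L0/(IC50 + L0)) / WT0.

Parameters vary between subjects on log or scaled-logit scales, with
ECOG status shifting baseline appetite and sex shifting baseline
weight. Estimation is Monte-Carlo maximum marginal likelihood on top of
a batched MAP-EM pass (see `docs/methods.md`). On top of the fitted
model the package provides:

* **virtual studies** under parameter uncertainty, mapping appetite
  change to the 3.5-kg weight change used in cachexia trials;
* a **dropout-corrected visual predictive check** and goodness-of-fit
  diagnostics;
* a **survival layer**: Cox models of the trajectory parameters
  (per-SD hazard ratios), LASSO covariate selection (5-fold CV,
  one-SE rule), Kaplan–Meier/log-rank reporting, and the
  **clinically-meaningful-cutoff scan** — the lowest predicted
  appetite-loss cutoff at a 1- or 3-month landmark with p < 0.05 and
  HR > 1;
* a **synthetic-cohort generator** emulating a recovering
  (post-chemoradiotherapy) and a chemotherapy (3-weekly docetaxel)
  NSCLC trial arm, with covariates, survival-linked terminal dropout
  and trial-faithful visit schedules, since the original trial data
  are licensed and not redistributable.

## Worked example

```python
from appwt import (generate_cohort, apply_exclusions, fit_population,
                   FitConfig, run_virtual_studies,
                   appetite_equivalent_of_weight_change)
from appwt.survival import survival_frame, parameter_forest, threshold_scan

cohort = generate_cohort("chemotherapy", 150, seed=2)
cohort, report = apply_exclusions(cohort)      # <2 appetite or weight obs
fit = fit_population(cohort, FitConfig(seed=2))

summary = run_virtual_studies(fit, n_replicates=200, n_subjects=150,
                              horizon=400.0, seed=3)
eq = appetite_equivalent_of_weight_change(summary, target_kg=3.5,
                                          direction="loss")
print(f"{eq.magnitude_mm:.0f} mm loss (90% CI {abs(eq.ci_high):.0f}"
      f"-{abs(eq.ci_low):.0f}) ~ 3.5 kg weight loss")

surv = survival_frame(cohort)
forest = parameter_forest(fit, surv)
print(forest.table.loc[["SLP", "PMAX"], ["hr", "p"]])
scan = threshold_scan(fit, surv, landmark=90.0, quantity="appetite")
print("meaningful 3-month appetite-loss cutoff:", scan.selected_cutoff, "mm")
```

This prints (numbers vary with the seed):

```
53 mm loss (90% CI 55-52) ~ 3.5 kg weight loss
                 hr         p
covariate
SLP        1.324885  0.007242
PMAX       0.878428  0.201711
meaningful 3-month appetite-loss cutoff: 0.0 mm
```

Read: in this virtual docetaxel cohort a ~53-mm score increase
accompanies a 3.5-kg weight loss by the time the median curve crosses
the target; a one-SD faster appetite-loss rate carries a ~32% higher
death hazard while stronger improvement trends protective; and because
the generator ties hazard smoothly to the loss rate, *any* predicted
loss at 3 months already separates survival, so the scan's lowest
significant cutoff is 0 mm. The 1-month scan typically selects nothing
here — predicted 30-day losses are small in this population — which is
the honest output of the rule, not a failure.

The same API drives the recovering profile in the `gain` direction
(appetite improvement against a 3.5-kg weight gain), and
`appwt.diagnostics.vpc` produces the dropout-corrected predictive
check. A one-command version of the whole analysis is available as
`appwt run --config run.yaml` (see `appwt --help` for the stagewise
subcommands).

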