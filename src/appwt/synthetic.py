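"""Virtual NSCLC cohorts with the statistical structure the analysis assumes.

Two profiles are provided:

* ``recovering`` — patients off chemoradiotherapy under supportive care:
  good baseline appetite, early appetite improvement followed by a slow
  late decline, net weight gain; appetite visits at baseline, weeks
  2/5/8 and then every 6 weeks, weekly weights for 8 weeks then every
  6 weeks.
* ``chemotherapy`` — patients on 3-weekly docetaxel: worse baseline
  appetite, persistent appetite loss and weight loss; appetite at
  baseline, cycles 2 and 4 and end of treatment, weight every cycle.

Individual parameters are drawn on transformed scales (log-normal for
rates/scales, scaled-logit for bounded parameters), with ECOG shifting
baseline appetite upward (worse) on the logit scale and female subjects
having proportionally lower baseline weight.  Overall survival comes
from a Weibull proportional-hazards process whose log-hazard depends on
the individual's standardized appetite-trajectory parameters (higher
appetite-loss rate -> worse survival, larger improvement -> better) and
on smoking / ECOG.  Dropout is terminal: observations cease a fixed lead
time before death, so the dropout-corrected visual predictive check has
something to correct.

All randomness flows through ``numpy.random.Generator`` (PCG64) seeded
explicitly, so cohorts are bit-reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _transforms as tr
from .data_model import (APPETITE, MONTH_DAYS, WEIGHT, CohortDataset,
                         Covariates, Observation, SubjectRecord,
                         SurvivalOutcome)
from .structural import (AppetiteParameters, IndividualParameters,
                         WeightParameters, appetite_at, clamp_score,
                         weight_at)

PROFILES = ("recovering", "chemotherapy")


@dataclass
class PopulationParameters:
    """Population-level description of one cohort.

    ``omega`` holds between-subject standard deviations on the
    transformed scales, keyed by parameter name; parameters absent from
    ``omega`` do not vary between subjects.  ``beta_ecog_l0`` shifts the
    logit of baseline appetite per ECOG level (positive = worse appetite
    with higher ECOG); ``beta_sex_wt0`` is the proportional reduction of
    baseline weight for female subjects.  Residual error is additive for
    appetite (mm) and proportional for weight.
    """

    typical: IndividualParameters
    omega: dict = field(default_factory=dict)
    beta_ecog_l0: float = 0.0
    beta_sex_wt0: float = 0.0
    sigma_appetite: float = 6.0
    sigma_weight: float = 0.015

    def __post_init__(self):
        for k, v in self.omega.items():
            if k not in tr.PARAMETER_NAMES:
                raise ValueError(f"unknown parameter {k!r} in omega")
            if v < 0:
                raise ValueError(f"omega[{k}] must be >= 0, got {v}")
        if not (0.0 <= self.beta_sex_wt0 < 1.0):
            raise ValueError("beta_sex_wt0 must lie in [0, 1)")
        if self.sigma_appetite <= 0 or self.sigma_weight <= 0:
            raise ValueError("residual sigmas must be > 0")

    def to_dict(self) -> dict:
        return {
            "typical": self.typical.as_dict(),
            "omega": dict(self.omega),
            "beta_ecog_l0": self.beta_ecog_l0,
            "beta_sex_wt0": self.beta_sex_wt0,
            "sigma_appetite": self.sigma_appetite,
            "sigma_weight": self.sigma_weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        return cls(
            typical=IndividualParameters.from_dict(d["typical"]),
            omega=dict(d.get("omega", {})),
            beta_ecog_l0=float(d.get("beta_ecog_l0", 0.0)),
            beta_sex_wt0=float(d.get("beta_sex_wt0", 0.0)),
            sigma_appetite=float(d.get("sigma_appetite", 6.0)),
            sigma_weight=float(d.get("sigma_weight", 0.015)),
        )


@dataclass(frozen=True)
class VisitSchedule:
    appetite_times: tuple
    weight_times: tuple

    def __post_init__(self):
        for name, times in (("appetite", self.appetite_times), ("weight", self.weight_times)):
            arr = np.asarray(times, dtype=float)
            if arr.size == 0 or arr[0] != 0.0 or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} times must start at 0 and be strictly increasing")


@dataclass
class SurvivalGeneratorSpec:
    """Weibull proportional-hazards survival generator.

    The log hazard is a linear combination of the subject's standardized
    transformed SLP and PMAX (standardized against the generating
    population), smoking status and ECOG level.  ``censor_days`` is the
    administrative censoring horizon; ``dropout_lead_days`` is how long
    before death longitudinal observation stops.
    """

    shape: float = 1.5
    scale_days: float = 455.0
    coef_slp: float = 0.35
    coef_pmax: float = -0.25
    coef_smoking_current: float = 0.25
    coef_smoking_former: float = 0.10
    coef_ecog: float = 0.30
    censor_days: float = 1100.0
    dropout_lead_days: float = 30.0

    def __post_init__(self):
        if self.shape <= 0 or self.scale_days <= 0:
            raise ValueError("Weibull shape and scale must be > 0")

    def log_hazard(self, ind: IndividualParameters, cov: Covariates,
                   pop: PopulationParameters) -> float:
        lp = 0.0
        for name, coef in (("SLP", self.coef_slp), ("PMAX", self.coef_pmax)):
            om = pop.omega.get(name, 0.0)
            if om > 0 and coef != 0.0:
                z = (float(tr.transform(name, ind.as_dict()[name]))
                     - float(tr.transform(name, pop.typical.as_dict()[name]))) / om
                lp += coef * z
        if cov.smoking == "current":
            lp += self.coef_smoking_current
        elif cov.smoking == "former":
            lp += self.coef_smoking_former
        if cov.ecog is not None:
            lp += self.coef_ecog * cov.ecog
        return lp


# --------------------------------------------------------------------------
# Default study conditions

def recovering_population() -> PopulationParameters:
    return PopulationParameters(
        typical=IndividualParameters.from_dict({
            "L0": 25.0, "SLP": 2e-3, "PMAX": 16.0, "Kp": 0.03,
            "WT0": 74.0, "Kin": 0.9, "Imax": 0.35, "IC50": 40.0,
        }),
        omega={"L0": 0.35, "SLP": 0.35, "PMAX": 0.45, "WT0": 0.18, "Imax": 0.40},
        beta_ecog_l0=0.35,
        beta_sex_wt0=0.188,
        sigma_appetite=6.0,
        sigma_weight=0.015,
    )


def chemotherapy_population() -> PopulationParameters:
    return PopulationParameters(
        typical=IndividualParameters.from_dict({
            "L0": 40.0, "SLP": 0.038, "PMAX": 12.0, "Kp": 0.02,
            "WT0": 71.0, "Kin": 0.9, "Imax": 0.35, "IC50": 40.0,
        }),
        omega={"L0": 0.35, "SLP": 0.40, "PMAX": 0.50, "WT0": 0.18, "Imax": 0.40},
        beta_ecog_l0=0.35,
        beta_sex_wt0=0.113,
        sigma_appetite=6.0,
        sigma_weight=0.015,
    )


def default_population(profile: str) -> PopulationParameters:
    if profile == "recovering":
        return recovering_population()
    if profile == "chemotherapy":
        return chemotherapy_population()
    raise ValueError(f"unknown profile {profile!r}")


def recovering_schedule(horizon_days: float = 420.0) -> VisitSchedule:
    app = [0.0, 14.0, 35.0, 56.0]
    t = 91.0
    while t <= horizon_days:
        app.append(t)
        t += 42.0
    wt = [float(d) for d in range(0, 57, 7)]
    t = 91.0
    while t <= horizon_days:
        wt.append(t)
        t += 42.0
    return VisitSchedule(appetite_times=tuple(app), weight_times=tuple(wt))


def chemotherapy_schedule(n_cycles: int = 8) -> VisitSchedule:
    end = 21.0 * n_cycles
    app = (0.0, 21.0, 63.0, end)
    wt = tuple(21.0 * c for c in range(n_cycles + 1))
    return VisitSchedule(appetite_times=app, weight_times=wt)


def default_schedule(profile: str) -> VisitSchedule:
    return recovering_schedule() if profile == "recovering" else chemotherapy_schedule()


def default_survival_spec(profile: str) -> SurvivalGeneratorSpec:
    # scales calibrated so the MARGINAL median OS (averaging the covariate
    # log-hazards) matches the trial arms: ~21 months recovering, ~11.7
    # months under docetaxel
    if profile == "recovering":
        return SurvivalGeneratorSpec(shape=1.5, scale_days=1065.0, censor_days=2000.0)
    return SurvivalGeneratorSpec(shape=1.5, scale_days=563.0, censor_days=1100.0)


# Covariate frequencies mirroring the two trial populations.
COVARIATE_FREQUENCIES = {
    "recovering": {
        "male": 0.681,
        "ecog": {0: 0.422, 1: 0.578, 2: 0.0},
        "smoking": {"current": 0.931, "never": 0.069, "former": 0.0},
        "age_mean": 61.0, "age_sd": 9.0, "age_range": (24.0, 83.0),
    },
    "chemotherapy": {
        "male": 0.639,
        "ecog": {0: 0.342, 1: 0.611, 2: 0.047},
        "smoking": {"current": 0.211, "never": 0.247, "former": 0.542},
        "age_mean": 61.0, "age_sd": 9.0, "age_range": (27.0, 80.0),
    },
}


def sample_covariates(profile: str, rng: np.random.Generator) -> Covariates:
    f = COVARIATE_FREQUENCIES[profile]
    sex = "male" if rng.random() < f["male"] else "female"
    ecog_levels = list(f["ecog"])
    ecog = int(rng.choice(ecog_levels, p=[f["ecog"][k] for k in ecog_levels]))
    smoke_levels = list(f["smoking"])
    smoking = str(rng.choice(smoke_levels, p=[f["smoking"][k] for k in smoke_levels]))
    lo, hi = f["age_range"]
    age = float(np.clip(rng.normal(f["age_mean"], f["age_sd"]), lo, hi))
    return Covariates(sex=sex, ecog=ecog, smoking=smoking, age=age)


# --------------------------------------------------------------------------
# Sampling

def prior_mean_z(pop: PopulationParameters, cov: Covariates) -> dict:
    """Transformed-scale prior means for one subject given covariates."""
    z = {name: float(tr.transform(name, v)) for name, v in pop.typical.as_dict().items()}
    if cov.ecog is not None:
        z["L0"] += pop.beta_ecog_l0 * cov.ecog
    if cov.sex == "female" and pop.beta_sex_wt0 > 0:
        z["WT0"] += math.log(1.0 - pop.beta_sex_wt0)
    return z


def sample_individual(pop: PopulationParameters, cov: Covariates,
                      rng: np.random.Generator) -> IndividualParameters:
    """Draw one subject's parameters on the transformed scales."""
    mean_z = prior_mean_z(pop, cov)
    values = {}
    for name in tr.PARAMETER_NAMES:
        om = pop.omega.get(name, 0.0)
        z = mean_z[name] + (om * rng.standard_normal() if om > 0 else 0.0)
        typ = pop.typical.as_dict()[name]
        if typ == 0.0 and om == 0.0:
            values[name] = 0.0  # degenerate: e.g. SLP pinned at zero
        else:
            values[name] = float(tr.untransform(name, z))
    return IndividualParameters.from_dict(values)


def simulate_subject(ind: IndividualParameters, schedule: VisitSchedule,
                     sigma_appetite: float, sigma_weight: float,
                     rng: np.random.Generator,
                     weight_floor: float = 1.0) -> list[Observation]:
    """Noisy observations at the scheduled visit times.

    Appetite: clamp(L(t)) + additive Gaussian noise, re-clamped to the
    instrument range.  Weight: WT(t) * (1 + proportional Gaussian noise),
    floored at ``weight_floor`` kg.
    """
    obs = []
    app_t = np.asarray(schedule.appetite_times)
    app_pred = clamp_score(appetite_at(ind.appetite, app_t))
    noise = sigma_appetite * rng.standard_normal(app_t.size) if sigma_appetite > 0 else 0.0
    app_val = clamp_score(app_pred + noise)
    for t, v in zip(app_t, np.atleast_1d(app_val)):
        obs.append(Observation(time=float(t), kind=APPETITE, value=float(v)))

    wt_t = np.asarray(schedule.weight_times)
    wt_pred = weight_at(ind, wt_t)
    noise = sigma_weight * rng.standard_normal(wt_t.size) if sigma_weight > 0 else 0.0
    wt_val = np.maximum(wt_pred * (1.0 + noise), weight_floor)
    for t, v in zip(wt_t, wt_val):
        obs.append(Observation(time=float(t), kind=WEIGHT, value=float(v)))
    return sorted(obs, key=lambda o: (o.time, o.kind))


def simulate_survival_and_dropout(
    ind: IndividualParameters, spec: SurvivalGeneratorSpec,
    schedule: VisitSchedule, rng: np.random.Generator,
    pop: Optional[PopulationParameters] = None,
    cov: Optional[Covariates] = None,
) -> tuple[SurvivalOutcome, VisitSchedule]:
    """Draw a survival outcome and truncate the visit schedule.

    Event times follow Weibull(shape, scale) with the individual's
    proportional log hazard; dropout occurs ``dropout_lead_days`` before
    death (never before baseline), and observation stops at
    min(dropout, event, administrative censoring).
    """
    cov = cov or Covariates()
    lp = spec.log_hazard(ind, cov, pop) if pop is not None else (
        SurvivalGeneratorSpec.log_hazard(spec, ind, cov,
                                         PopulationParameters(typical=ind)))
    u = rng.random()
    event_days = spec.scale_days * (-math.log(max(u, 1e-300)) / math.exp(lp)) ** (1.0 / spec.shape)
    censored = event_days > spec.censor_days
    time_days = min(event_days, spec.censor_days)
    outcome = SurvivalOutcome(
        time_months=max(time_days, 1e-6) / MONTH_DAYS, event=not censored,
    )
    dropout_days = max(event_days - spec.dropout_lead_days, 0.0)
    horizon = min(dropout_days, event_days, spec.censor_days)
    app = tuple(t for t in schedule.appetite_times if t <= horizon)
    wt = tuple(t for t in schedule.weight_times if t <= horizon)
    truncated = None
    if app and wt:
        truncated = VisitSchedule(appetite_times=app, weight_times=wt)
    return outcome, truncated


def _simulate_subjects(pop: PopulationParameters, spec: Optional[SurvivalGeneratorSpec],
                       covariates: Sequence[Covariates], schedule: VisitSchedule,
                       rng: np.random.Generator, id_prefix: str = "S",
                       id_offset: int = 0):
    """Shared simulation core for cohort generation and VPC replicates.

    Draw order per subject: parameters, survival, appetite noise, weight
    noise — fixed so that a replicate driven by the same seed sequence
    reproduces a generated cohort exactly.
    """
    subjects, truth = [], {}
    for i, cov in enumerate(covariates):
        sid = f"{id_prefix}{id_offset + i + 1:04d}"
        ind = sample_individual(pop, cov, rng)
        surv, kept = None, schedule
        if spec is not None:
            surv, kept = simulate_survival_and_dropout(ind, spec, schedule, rng,
                                                       pop=pop, cov=cov)
        obs = []
        if kept is not None:
            obs = simulate_subject(ind, kept, pop.sigma_appetite, pop.sigma_weight, rng)
        subjects.append(SubjectRecord(subject_id=sid, covariates=cov,
                                      observations=obs, survival=surv))
        truth[sid] = ind
    return subjects, truth


def generate_cohort(
    profile: str, n: int, pop: Optional[PopulationParameters] = None,
    spec: Optional[SurvivalGeneratorSpec] = None,
    schedule: Optional[VisitSchedule] = None,
    seed: int = 0, return_truth: bool = False,
):
    """Generate a virtual cohort of ``n`` subjects.

    With ``return_truth=True`` also returns the map subject_id ->
    true :class:`IndividualParameters` for recovery testing.
    """
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {PROFILES}, got {profile!r}")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    pop = pop or default_population(profile)
    spec = spec if spec is not None else default_survival_spec(profile)
    schedule = schedule or default_schedule(profile)
    ss_cov, ss_obs = np.random.SeedSequence(seed).spawn(2)
    cov_rng = np.random.default_rng(ss_cov)
    covariates = [sample_covariates(profile, cov_rng) for _ in range(n)]
    subjects, truth = _simulate_subjects(pop, spec, covariates, schedule,
                                         np.random.default_rng(ss_obs))
    cohort = CohortDataset(label=profile, subjects=subjects)
    return (cohort, truth) if return_truth else cohort
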