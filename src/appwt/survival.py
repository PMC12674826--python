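"""Survival layer: Cox associations of model parameters with overall
survival, LASSO covariate selection, the clinically-meaningful-cutoff
scan, and Kaplan-Meier / log-rank reporting.

Model parameters enter Cox models as standardized transformed
empirical-Bayes estimates, so hazard ratios are per standard deviation.
The cutoff scan classifies subjects by their model-predicted appetite
loss (or weight loss) at a landmark day, fits a Cox model per cutoff
adjusted for the LASSO-selected clinical covariates, and selects the
lowest cutoff with p < 0.05 and HR > 1 — the literal selection rule,
with no multiplicity correction (an optional permutation-adjusted p is
available).  Only subjects surviving past the landmark enter a landmark
scan, avoiding immortal-time bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from . import _transforms as tr
from .data_model import CohortDataset
from .fitting import PopulationFit
from .simulation import predicted_change_at

FOREST_PARAMETERS = ("L0", "PMAX", "SLP", "WT0", "Imax")


class CollinearityError(ValueError):
    """Design matrix is rank deficient (e.g. duplicated parameter column)."""


@dataclass
class CoxResult:
    table: pd.DataFrame     # index: covariate; coef, hr, ci_low, ci_high, p
    loglik: float
    n: int
    n_events: int
    flagged: bool = False   # convergence trouble / possible separation

    def hr(self, name: str) -> float:
        return float(self.table.loc[name, "hr"])

    def p(self, name: str) -> float:
        return float(self.table.loc[name, "p"])


@dataclass
class LassoSelection:
    selected: list
    alphas: np.ndarray
    cv_mean: np.ndarray     # mean CV partial-likelihood deviance per alpha
    cv_se: np.ndarray
    alpha_min: float
    alpha_1se: float
    coef_1se: dict


@dataclass
class ThresholdScanResult:
    landmark: float
    quantity: str                      # "appetite" | "weight"
    grid: np.ndarray
    table: pd.DataFrame                # cutoff, hr, ci_low, ci_high, p, n_above, n_below, skipped
    selected_cutoff: Optional[float]   # lowest cutoff with p<0.05 and HR>1
    adjusted: tuple = ()
    permutation_p: Optional[float] = None


@dataclass
class KMResult:
    curves: dict            # group label -> DataFrame(time, survival, ci_low, ci_high, at_risk)
    statistic: float
    pvalue: float


def survival_frame(cohort: CohortDataset, time_unit: str = "days") -> pd.DataFrame:
    """Per-subject survival table with dummy-coded clinical covariates.

    Subjects without a survival outcome are dropped; covariate columns
    hold NaN where the covariate is missing (no imputation).
    """
    rows = []
    for s in cohort.subjects:
        if s.survival is None:
            continue
        c = s.covariates
        rows.append({
            "subject_id": s.subject_id,
            "time": s.survival.time_days if time_unit == "days" else s.survival.time_months,
            "event": int(s.survival.event),
            "female": {None: np.nan, "male": 0.0, "female": 1.0}[c.sex],
            "ecog": np.nan if c.ecog is None else float(c.ecog),
            "smoking_current": np.nan if c.smoking is None else float(c.smoking == "current"),
            "smoking_former": np.nan if c.smoking is None else float(c.smoking == "former"),
            "age": np.nan if c.age is None else float(c.age),
        })
    return pd.DataFrame(rows).set_index("subject_id")


def cox_fit(df: pd.DataFrame, covariates: Sequence[str],
            duration_col: str = "time", event_col: str = "event") -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling, Wald inference)."""
    covariates = list(covariates)
    data = df[[duration_col, event_col] + covariates].dropna()
    n_events = int(data[event_col].sum())
    if n_events == 0:
        raise ValueError("no events in the data")
    flagged = False
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        except ConvergenceError:
            flagged = True
            cph = CoxPHFitter(penalizer=1e-5)
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            flagged = True
    summ = cph.summary
    table = pd.DataFrame({
        "coef": summ["coef"],
        "hr": summ["exp(coef)"],
        "ci_low": np.exp(summ["coef lower 95%"]),
        "ci_high": np.exp(summ["coef upper 95%"]),
        "p": summ["p"],
    })
    if np.any(np.abs(summ["coef"]) > 10):
        flagged = True
    return CoxResult(table=table, loglik=float(cph.log_likelihood_),
                     n=len(data), n_events=n_events, flagged=flagged)


def _breslow_pl(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                event: np.ndarray) -> float:
    """Breslow partial log-likelihood (used only for CV deviance)."""
    order = np.argsort(-time)
    X, time, event = X[order], time[order], event[order]
    eta = X @ beta
    m = eta.max()
    log_risk = np.log(np.cumsum(np.exp(eta - m))) + m
    # ties share the full risk set at their common time
    same_as_next = np.zeros(len(time), dtype=bool)
    same_as_next[:-1] = time[:-1] == time[1:]
    for i in range(len(time) - 2, -1, -1):
        if same_as_next[i]:
            log_risk[i] = log_risk[i + 1]
    return float(np.sum((eta - log_risk)[event.astype(bool)]))


def cox_lasso_path(df: pd.DataFrame, candidates: Sequence[str],
                   duration_col: str = "time", event_col: str = "event",
                   alphas: Optional[np.ndarray] = None):
    """Full-data L1 Cox path on standardized covariates.

    Returns (fitted estimator, alphas, feature means, feature SDs).
    """
    data = df[[duration_col, event_col] + list(candidates)].dropna()
    X = data[list(candidates)].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    y = Surv.from_arrays(event=data[event_col].astype(bool),
                         time=data[duration_col])
    est = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=50,
                                 alpha_min_ratio=0.01,
                                 alphas=None if alphas is None else list(alphas))
    est.fit(Xs, y)
    return est, np.asarray(est.alphas_), mu, sd, data


def lasso_select(df: pd.DataFrame, candidates: Sequence[str],
                 duration_col: str = "time", event_col: str = "event",
                 folds: int = 5, seed: int = 0) -> LassoSelection:
    """L1-penalized Cox with K-fold cross-validated deviance.

    Deviance per fold follows Verweij & van Houwelingen:
    ``-2 * (pl_all(beta) - pl_train(beta))``.  The returned covariate set
    holds the nonzero coefficients at the largest penalty within one
    standard error of the minimum mean deviance (lambda_1se).
    """
    candidates = list(candidates)
    if not candidates:
        return LassoSelection(selected=[], alphas=np.array([]),
                              cv_mean=np.array([]), cv_se=np.array([]),
                              alpha_min=float("nan"), alpha_1se=float("nan"),
                              coef_1se={})
    est, alphas, mu, sd, data = cox_lasso_path(df, candidates,
                                               duration_col, event_col)
    n_events = int(data[event_col].sum())
    if n_events < folds:
        raise ValueError(f"need at least {folds} events for {folds}-fold CV")
    X = (data[candidates].to_numpy(dtype=float) - mu) / sd
    time = data[duration_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=float)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(alphas)))
    for f, (tr_idx, _te_idx) in enumerate(kf.split(X)):
        est_f = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas))
        y_tr = Surv.from_arrays(event=event[tr_idx].astype(bool),
                                time=time[tr_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est_f.fit(X[tr_idx], y_tr)
        fitted = np.asarray(est_f.alphas_)
        for a, alpha in enumerate(alphas):
            # coxnet may truncate its path; reuse the closest fitted alpha
            j = int(np.argmin(np.abs(np.log(fitted) - np.log(alpha))))
            beta = est_f.coef_[:, j]
            pl_all = _breslow_pl(beta, X, time, event)
            pl_tr = _breslow_pl(beta, X[tr_idx], time[tr_idx], event[tr_idx])
            dev[f, a] = -2.0 * (pl_all - pl_tr)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_se[i_min]
    ok = np.nonzero(cv_mean <= threshold)[0]
    i_1se = int(ok[np.argmax(alphas[ok])])
    coefs = est.coef_[:, i_1se]
    selected = [c for c, b in zip(candidates, coefs) if abs(b) > 1e-10]
    return LassoSelection(selected=selected, alphas=alphas, cv_mean=cv_mean,
                          cv_se=cv_se, alpha_min=float(alphas[i_min]),
                          alpha_1se=float(alphas[i_1se]),
                          coef_1se={c: float(b) for c, b in zip(candidates, coefs)})


def standardized_parameter_frame(fit: PopulationFit,
                                 params: Sequence[str] = FOREST_PARAMETERS) -> pd.DataFrame:
    """Standardized transformed EBEs, one row per subject."""
    params = list(params)
    sids = list(fit.ebes)
    data = np.empty((len(sids), len(params)))
    for i, sid in enumerate(sids):
        d = fit.ebes[sid].as_dict()
        data[i] = [float(tr.transform(p, d[p])) for p in params]
    sd = data.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame((data - data.mean(axis=0)) / sd, index=sids,
                        columns=params)


def parameter_forest(fit: PopulationFit, surv: pd.DataFrame,
                     adjust: Sequence[str] = (),
                     params: Sequence[str] = FOREST_PARAMETERS) -> CoxResult:
    """Multivariable Cox fit of standardized model parameters plus the
    selected clinical covariates (forest-plot table)."""
    params = list(params)
    Z = standardized_parameter_frame(fit, params)
    if Z.columns.duplicated().any():
        raise CollinearityError(f"duplicated parameter columns: "
                                f"{sorted(set(Z.columns[Z.columns.duplicated()]))}")
    df = surv.join(Z, how="inner")
    cols = params + list(adjust)
    mat = df[cols].dropna().to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat - mat.mean(axis=0)) < mat.shape[1]:
        raise CollinearityError("rank-deficient design (collinear columns)")
    return cox_fit(df, cols)


def threshold_scan(fit: PopulationFit, surv: pd.DataFrame, landmark: float,
                   quantity: str = "appetite",
                   grid: Optional[np.ndarray] = None,
                   adjust: Sequence[str] = (),
                   min_group: int = 5,
                   n_permutations: int = 0,
                   seed: int = 0) -> ThresholdScanResult:
    """Scan cutoffs of model-predicted loss at a landmark against OS.

    ``quantity="appetite"`` classifies by predicted appetite-score
    increase (mm) at the landmark; ``"weight"`` by predicted weight loss
    (kg, positive = loss).  Cutoffs producing a group smaller than
    ``min_group`` on either side are skipped.  Landmark eligibility:
    only subjects surviving beyond the landmark are analysed.
    """
    if quantity not in ("appetite", "weight"):
        raise ValueError("quantity must be 'appetite' or 'weight'")
    if grid is None:
        grid = (np.arange(0.0, 15.1, 1.0) if quantity == "appetite"
                else np.arange(0.0, 5.01, 0.5))
    grid = np.asarray(grid, dtype=float)

    losses = {}
    for sid in surv.index:
        if sid not in fit.ebes:
            continue
        d_app, d_wt = predicted_change_at(fit, sid, landmark)
        losses[sid] = d_app if quantity == "appetite" else -d_wt
    df = surv.loc[[s for s in surv.index if s in losses]].copy()
    df["loss"] = [losses[s] for s in df.index]
    df = df[df["time"] > landmark]

    rows = []
    selected = None
    rng = np.random.default_rng(seed)
    for c in grid:
        above = df["loss"] >= c
        row = {"cutoff": float(c), "n_above": int(above.sum()),
               "n_below": int((~above).sum()), "hr": np.nan,
               "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
               "skipped": False}
        if row["n_above"] < min_group or row["n_below"] < min_group:
            row["skipped"] = True
            rows.append(row)
            continue
        sub = df.copy()
        sub["group"] = above.astype(float)
        try:
            res = cox_fit(sub, ["group"] + list(adjust))
        except (ValueError, ConvergenceError):
            row["skipped"] = True
            rows.append(row)
            continue
        row.update(hr=res.hr("group"), ci_low=float(res.table.loc["group", "ci_low"]),
                   ci_high=float(res.table.loc["group", "ci_high"]),
                   p=res.p("group"))
        if selected is None and row["p"] < 0.05 and row["hr"] > 1.0:
            selected = float(c)
        rows.append(row)

    perm_p = None
    if n_permutations > 0:
        observed = np.nanmin([r["p"] for r in rows if not r["skipped"]] or [np.nan])
        count = 0
        for _ in range(n_permutations):
            dperm = df.copy()
            dperm["loss"] = rng.permutation(df["loss"].to_numpy())
            pmin = np.inf
            for c in grid:
                above = dperm["loss"] >= c
                if above.sum() < min_group or (~above).sum() < min_group:
                    continue
                dperm["group"] = above.astype(float)
                try:
                    res = cox_fit(dperm, ["group"] + list(adjust))
                except (ValueError, ConvergenceError):
                    continue
                if res.hr("group") > 1.0:
                    pmin = min(pmin, res.p("group"))
            if pmin <= observed:
                count += 1
        perm_p = (count + 1) / (n_permutations + 1)

    return ThresholdScanResult(landmark=landmark, quantity=quantity, grid=grid,
                               table=pd.DataFrame(rows),
                               selected_cutoff=selected,
                               adjusted=tuple(adjust),
                               permutation_p=perm_p)


def km_logrank(durations, events, groups) -> KMResult:
    """Two-group Kaplan-Meier curves and log-rank test."""
    from lifelines.statistics import logrank_test

    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {len(labels)}")
    curves = {}
    for lab in labels:
        m = groups == lab
        if m.sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
        km = KaplanMeierFitter()
        km.fit(durations[m], events[m], label=str(lab))
        ci = km.confidence_interval_
        curves[lab] = pd.DataFrame({
            "time": km.survival_function_.index,
            "survival": km.survival_function_.iloc[:, 0].to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
            "at_risk": km.event_table["at_risk"].reindex(
                km.survival_function_.index).to_numpy(),
        })
    m0 = groups == labels[0]
    res = logrank_test(durations[m0], durations[~m0],
                       events[m0], events[~m0])
    return KMResult(curves=curves, statistic=float(res.test_statistic),
                    pvalue=float(res.p_value))
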