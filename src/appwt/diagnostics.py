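"""Goodness-of-fit tables and the dropout-corrected visual predictive check.

The VPC simulates replicate cohorts from the population estimates using
each subject's own design (planned visit times and covariates) together
with the configured survival/dropout process, so simulated observation
sets thin over time the way the data do.  Binned observed percentiles
(10th/50th/90th) are compared with the 90% prediction interval of the
same percentiles across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import APPETITE, WEIGHT, CohortDataset
from .fitting import PopulationFit
from .structural import appetite_at, clamp_score, weight_at
from .synthetic import (SurvivalGeneratorSpec, VisitSchedule,
                        _simulate_subjects)


@dataclass
class GofResult:
    table: pd.DataFrame  # kind, subject_id, time, observed, ipred
    slopes: dict         # kind -> (slope, intercept) of obs ~ ipred

    def pairs(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind]


def goodness_of_fit(fit: PopulationFit, cohort: CohortDataset) -> GofResult:
    """Observation vs individual-prediction pairs from the EBE parameters."""
    rows = []
    for s in cohort.subjects:
        if s.subject_id not in fit.ebes:
            continue
        ind = fit.ebes[s.subject_id]
        ta, ya = s.times_values(APPETITE)
        if ta.size:
            pred = clamp_score(appetite_at(ind.appetite, ta))
            rows += [{"kind": APPETITE, "subject_id": s.subject_id,
                      "time": t, "observed": y, "ipred": p}
                     for t, y, p in zip(ta, ya, np.atleast_1d(pred))]
        tw, yw = s.times_values(WEIGHT)
        if tw.size:
            pred = weight_at(ind, tw)
            rows += [{"kind": WEIGHT, "subject_id": s.subject_id,
                      "time": t, "observed": y, "ipred": p}
                     for t, y, p in zip(tw, yw, pred)]
    table = pd.DataFrame(rows)
    slopes = {}
    for kind in (APPETITE, WEIGHT):
        sub = table[table["kind"] == kind]
        if len(sub) >= 2 and np.ptp(sub["ipred"].to_numpy()) > 0:
            coef = np.polyfit(sub["ipred"], sub["observed"], 1)
            slopes[kind] = (float(coef[0]), float(coef[1]))
    return GofResult(table=table, slopes=slopes)


@dataclass
class VpcResult:
    kind: str
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    observed: np.ndarray   # (n_bins, 3): 10th/50th/90th percentiles
    sim_lo: np.ndarray     # (n_bins, 3): lower 90% PI of each percentile
    sim_hi: np.ndarray     # (n_bins, 3)
    n_replicates: int
    percentiles: tuple = (10.0, 50.0, 90.0)

    def median_within_pi(self) -> float:
        """Fraction of bins whose observed median lies inside the simulated
        90% prediction interval of the median."""
        ok = (self.observed[:, 1] >= self.sim_lo[:, 1]) & \
             (self.observed[:, 1] <= self.sim_hi[:, 1])
        return float(np.mean(ok))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_mid": self.bin_mid})
        for i, p in enumerate(self.percentiles):
            df[f"obs_p{int(p)}"] = self.observed[:, i]
            df[f"sim_lo_p{int(p)}"] = self.sim_lo[:, i]
            df[f"sim_hi_p{int(p)}"] = self.sim_hi[:, i]
        return df


def _binned_percentiles(times, values, edges, pcts):
    out = np.full((len(edges) - 1, len(pcts)), np.nan)
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
    for b in range(len(edges) - 1):
        vals = values[idx == b]
        if vals.size:
            out[b] = np.percentile(vals, pcts)
    return out


def _collect(subjects, kind: str, change_from_baseline: bool):
    ts, vs = [], []
    for s in subjects:
        t, v = s.times_values(kind)
        if t.size == 0:
            continue
        if change_from_baseline:
            v = v - v[0]
        ts.append(t); vs.append(v)
    if not ts:
        return np.array([]), np.array([])
    return np.concatenate(ts), np.concatenate(vs)


def vpc(fit: PopulationFit, cohort: CohortDataset, schedule: VisitSchedule,
        dropout: Optional[SurvivalGeneratorSpec] = None,
        n_replicates: int = 1000, n_bins: int = 8, kind: str = WEIGHT,
        change_from_baseline: bool = False,
        seed: int = 0, percentiles=(10.0, 50.0, 90.0),
        replicate_entropy: Optional[Sequence] = None) -> VpcResult:
    """Dropout-corrected visual predictive check.

    ``schedule`` is the planned visit design (identical for all subjects
    here, matching the trial protocols); ``dropout`` the survival/dropout
    process simulated inside every replicate (None disables dropout).
    ``change_from_baseline`` subtracts each subject's first observation,
    matching the usual presentation of weight change over time.
    ``replicate_entropy`` optionally supplies one seed sequence per
    replicate, used to tie a replicate to a known generator stream in
    self-consistency checks.
    """
    obs_t, obs_v = _collect(cohort.subjects, kind, change_from_baseline)
    if obs_t.size == 0:
        raise ValueError(f"cohort holds no {kind!r} observations")

    # quantile bins on observed times; merge empty/duplicate bins
    qs = np.linspace(0.0, 100.0, n_bins + 1)
    edges = np.unique(np.percentile(obs_t, qs))
    if len(edges) < 2:
        edges = np.array([obs_t.min(), obs_t.max() + 1.0])
    edges[-1] += 1e-9
    pcts = np.asarray(percentiles)
    observed = _binned_percentiles(obs_t, obs_v, edges, pcts)

    covariates = [fit.covariates.get(s.subject_id, s.covariates)
                  for s in cohort.subjects]
    if replicate_entropy is None:
        replicate_entropy = np.random.SeedSequence(seed).spawn(n_replicates)
    elif len(replicate_entropy) != n_replicates:
        raise ValueError("need one entropy source per replicate")

    sims = np.full((n_replicates, len(edges) - 1, len(pcts)), np.nan)
    for r in range(n_replicates):
        rng = np.random.default_rng(replicate_entropy[r])
        subjects, _ = _simulate_subjects(fit.estimates, dropout, covariates,
                                         schedule, rng)
        ts, vs = _collect(subjects, kind, change_from_baseline)
        if ts.size:
            sims[r] = _binned_percentiles(ts, vs, edges, pcts)

    with np.errstate(invalid="ignore"):
        sim_lo = np.nanpercentile(sims, 5.0, axis=0)
        sim_hi = np.nanpercentile(sims, 95.0, axis=0)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return VpcResult(kind=kind, bin_edges=edges, bin_mid=mid,
                     observed=observed, sim_lo=sim_lo, sim_hi=sim_hi,
                     n_replicates=n_replicates, percentiles=tuple(pcts))


def plot_vpc(result: VpcResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = ["#7aa6d6", "#d66a6a", "#7aa6d6"]
    for i, p in enumerate(result.percentiles):
        ax.fill_between(result.bin_mid, result.sim_lo[:, i], result.sim_hi[:, i],
                        alpha=0.35, color=colors[i % 3], lw=0)
        ax.plot(result.bin_mid, result.observed[:, i], "-o", ms=3,
                color="#1f4e8c", lw=1.2,
                label=f"observed p{int(p)}" if i == 1 else None)
    ax.set_xlabel("time (days)")
    ax.set_ylabel(result.kind)
    ax.set_title(f"VPC ({result.kind}), {result.n_replicates} replicates")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_gof(result: GofResult, kind: str, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = result.pairs(kind)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(sub["ipred"], sub["observed"], s=6, alpha=0.4)
    lims = [min(sub["ipred"].min(), sub["observed"].min()),
            max(sub["ipred"].max(), sub["observed"].max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("individual prediction")
    ax.set_ylabel("observation")
    ax.set_title(kind)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
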