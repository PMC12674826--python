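"""End-to-end analysis pipeline with seed management and checkpointing.

Stages: simulate -> exclusions -> fit -> diagnostics -> virtual studies
-> equivalence -> survival (forest, cutoff scans, KM).  A single master
seed is fanned out to per-stage seeds through ``numpy.random.SeedSequence``
spawning, so stages are independently reproducible; every stage writes
its artifact plus an entry (seed, outputs, checksums) in the run
manifest, and a re-run with ``resume=True`` skips completed stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import synthetic
from .data_model import (CohortDataset, EmptyCohortError, apply_exclusions,
                         read_cohort, write_cohort)
from .diagnostics import goodness_of_fit, plot_gof, plot_vpc, vpc
from .fitting import FitConfig, PopulationFit, fit_population
from .simulation import (appetite_equivalent_of_weight_change,
                         predicted_change_at, run_virtual_studies)
from .survival import (km_logrank, lasso_select, parameter_forest,
                       survival_frame, threshold_scan)

STAGES = ("simulate", "exclusions", "fit", "diagnostics",
          "virtual_studies", "equivalence", "survival")

CLINICAL_CANDIDATES = ("female", "ecog", "smoking_current", "smoking_former", "age")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str
    master_seed: int = 0
    # cohort source: either a CSV path or a simulation profile
    cohort_path: Optional[str] = None
    profile: Optional[str] = None
    n_subjects: int = 200
    # fit settings
    fit: dict = field(default_factory=dict)
    # simulation settings
    n_replicates: int = 200
    vs_subjects: int = 150
    horizon: float = 420.0
    target_kg: float = 3.5
    direction: str = "loss"
    # survival settings
    landmarks: tuple = (30.0, 90.0)
    vpc_replicates: int = 200
    make_plots: bool = True

    def __post_init__(self):
        if (self.cohort_path is None) == (self.profile is None):
            raise ValueError("specify exactly one of cohort_path or profile")
        if self.profile is not None and self.profile not in synthetic.PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seeds(master_seed: int, n: int = len(STAGES)) -> dict:
    """Deterministic fan-out of the master seed to per-stage seeds."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(STAGES, children)}


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute the pipeline; returns the manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"config": dataclasses.asdict(config),
                "seeds": stage_seeds(config.master_seed), "stages": {}}
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh)
        if previous.get("config") == manifest["config"]:
            manifest["stages"] = previous.get("stages", {})

    def done(stage: str) -> bool:
        entry = manifest["stages"].get(stage)
        if not entry or entry.get("status") != "ok":
            return False
        return all(Path(p).exists() for p in entry.get("outputs", []))

    def record(stage: str, outputs: list, extra: Optional[dict] = None) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "seed": manifest["seeds"][stage],
            "outputs": [str(p) for p in outputs],
            "checksums": {str(p): _sha256(Path(p)) for p in outputs},
            "elapsed_s": round(time.time() - t_start, 2),
            **(extra or {}),
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    seeds = manifest["seeds"]

    # -- simulate / load ----------------------------------------------------
    cohort_file = out / "cohort.csv"
    truth_file = out / "cohort_truth.json"
    t_start = time.time()
    if not done("simulate"):
        try:
            if config.profile is not None:
                cohort, truth = synthetic.generate_cohort(
                    config.profile, config.n_subjects, seed=seeds["simulate"],
                    return_truth=True)
                write_cohort(cohort, cohort_file)
                with open(truth_file, "w") as fh:
                    json.dump({sid: p.as_dict() for sid, p in truth.items()},
                              fh, indent=2)
                record("simulate", [cohort_file, truth_file])
            else:
                cohort = read_cohort(config.cohort_path)
                write_cohort(cohort, cohort_file)
                record("simulate", [cohort_file], {"source": config.cohort_path})
        except Exception as exc:  # noqa: BLE001
            fail("simulate", exc)
    cohort = read_cohort(cohort_file,
                         label=config.profile or "custom")

    # -- exclusions ---------------------------------------------------------
    excl_file = out / "exclusions.json"
    t_start = time.time()
    if not done("exclusions"):
        try:
            cohort, report = apply_exclusions(cohort)
            with open(excl_file, "w") as fh:
                fh.write(report.to_json())
            write_cohort(cohort, out / "cohort_included.csv")
            record("exclusions", [excl_file, out / "cohort_included.csv"],
                   {"n_before": report.n_before, "n_after": report.n_after})
        except EmptyCohortError as exc:
            fail("exclusions", exc)
    cohort = read_cohort(out / "cohort_included.csv",
                         label=config.profile or "custom")

    # -- fit ----------------------------------------------------------------
    fit_file = out / "fit.json"
    t_start = time.time()
    if not done("fit"):
        try:
            fit_cfg = FitConfig(**config.fit, seed=seeds["fit"])
            fit = fit_population(cohort, fit_cfg)
            fit.to_json(fit_file)
            record("fit", [fit_file], {"converged": fit.converged,
                                       "loglik": fit.loglik})
        except Exception as exc:  # noqa: BLE001
            fail("fit", exc)
    fit = PopulationFit.from_json(fit_file)

    # -- diagnostics --------------------------------------------------------
    t_start = time.time()
    if not done("diagnostics"):
        try:
            gof = goodness_of_fit(fit, cohort)
            gof_file = out / "gof.csv"
            gof.table.to_csv(gof_file, index=False)
            schedule = synthetic.default_schedule(config.profile or "chemotherapy")
            spec = synthetic.default_survival_spec(config.profile or "chemotherapy")
            v = vpc(fit, cohort, schedule, dropout=spec,
                    n_replicates=config.vpc_replicates, seed=seeds["diagnostics"])
            vpc_file = out / "vpc.csv"
            v.to_frame().to_csv(vpc_file, index=False)
            outputs = [gof_file, vpc_file]
            if config.make_plots:
                plot_vpc(v, out / "vpc.png")
                for kind in ("appetite", "weight"):
                    plot_gof(gof, kind, out / f"gof_{kind}.png")
                outputs += [out / "vpc.png", out / "gof_appetite.png",
                            out / "gof_weight.png"]
            record("diagnostics", outputs,
                   {"vpc_median_coverage": v.median_within_pi(),
                    "gof_slopes": gof.slopes})
        except Exception as exc:  # noqa: BLE001
            fail("diagnostics", exc)

    # -- virtual studies ----------------------------------------------------
    vs_file = out / "virtual_studies.npz"
    t_start = time.time()
    if not done("virtual_studies"):
        try:
            summary = run_virtual_studies(
                fit, n_replicates=config.n_replicates,
                n_subjects=config.vs_subjects, horizon=config.horizon,
                seed=seeds["virtual_studies"])
            np.savez(vs_file, grid=summary.grid,
                     appetite_median=summary.appetite_median,
                     weight_median=summary.weight_median)
            record("virtual_studies", [vs_file])
        except Exception as exc:  # noqa: BLE001
            fail("virtual_studies", exc)

    # -- equivalence --------------------------------------------------------
    eq_file = out / "equivalence.json"
    t_start = time.time()
    if not done("equivalence"):
        try:
            from .simulation import VirtualStudySummary
            data = np.load(vs_file)
            summary = VirtualStudySummary(grid=data["grid"],
                                          appetite_median=data["appetite_median"],
                                          weight_median=data["weight_median"])
            eq = appetite_equivalent_of_weight_change(
                summary, target_kg=config.target_kg, direction=config.direction)
            with open(eq_file, "w") as fh:
                json.dump(dataclasses.asdict(eq), fh, indent=2)
            record("equivalence", [eq_file],
                   {"appetite_change_mm": eq.appetite_change_mm,
                    "ci": [eq.ci_low, eq.ci_high], "reached": eq.reached})
        except Exception as exc:  # noqa: BLE001
            fail("equivalence", exc)

    # -- survival -----------------------------------------------------------
    t_start = time.time()
    if not done("survival"):
        try:
            surv = survival_frame(cohort)
            results = {}
            candidates = [c for c in CLINICAL_CANDIDATES
                          if surv[c].notna().all() and surv[c].nunique() > 1]
            sel = lasso_select(surv, candidates, seed=seeds["survival"])
            results["lasso_selected"] = sel.selected
            forest = parameter_forest(fit, surv, adjust=sel.selected)
            forest_file = out / "forest.csv"
            forest.table.to_csv(forest_file)
            results["forest"] = {k: {"hr": float(forest.table.loc[k, "hr"]),
                                     "p": float(forest.table.loc[k, "p"])}
                                 for k in forest.table.index}
            scans = {}
            outputs = [forest_file]
            for lm in config.landmarks:
                scan = threshold_scan(fit, surv, landmark=lm,
                                      quantity="appetite", adjust=sel.selected)
                scan_file = out / f"scan_appetite_{int(lm)}d.csv"
                scan.table.to_csv(scan_file, index=False)
                outputs.append(scan_file)
                scans[f"appetite_{int(lm)}d"] = scan.selected_cutoff
                wscan = threshold_scan(fit, surv, landmark=lm,
                                       quantity="weight", adjust=sel.selected)
                wscan_file = out / f"scan_weight_{int(lm)}d.csv"
                wscan.table.to_csv(wscan_file, index=False)
                outputs.append(wscan_file)
                scans[f"weight_{int(lm)}d"] = wscan.selected_cutoff
                if scan.selected_cutoff is not None:
                    lm_df = surv[surv["time"] > lm]
                    grp = np.array(
                        [predicted_change_at(fit, s, lm)[0] >= scan.selected_cutoff
                         for s in lm_df.index])
                    if 0 < grp.sum() < len(grp):
                        km = km_logrank(lm_df["time"], lm_df["event"], grp)
                        results[f"km_{int(lm)}d"] = {
                            "statistic": km.statistic, "p": km.pvalue}
            results["selected_cutoffs"] = scans
            surv_file = out / "survival.json"
            with open(surv_file, "w") as fh:
                json.dump(results, fh, indent=2)
            outputs.append(surv_file)
            record("survival", outputs, {"selected_cutoffs": scans})
        except Exception as exc:  # noqa: BLE001
            fail("survival", exc)

    return manifest
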