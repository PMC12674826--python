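"""Domain types and longitudinal CSV I/O.

Datasets are held in a NONMEM-style long format: one row per observation
with a subject id, time (days since baseline), an observation-kind column
(``appetite`` scores in mm on the LCSS 0-100 visual-analogue scale, or
``weight`` in kg) and subject-constant covariate columns.  Overall
survival is stored in months at the I/O boundary and converted to days
internally.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

MONTH_DAYS = 30.4375

APPETITE = "appetite"
WEIGHT = "weight"
OBS_KINDS = (APPETITE, WEIGHT)

SEXES = ("male", "female")
SMOKING = ("never", "current", "former")
ECOG_LEVELS = (0, 1, 2)

DEFAULT_SCHEMA = {
    "id": "ID",
    "time": "TIME",
    "kind": "DVID",
    "value": "DV",
    "sex": "SEX",
    "ecog": "ECOG",
    "smoking": "SMOKING",
    "age": "AGE",
    "os_months": "OS_MONTHS",
    "os_event": "OS_EVENT",
}

MANDATORY_COLUMNS = ("id", "time", "kind", "value")


class SchemaError(ValueError):
    """A mandatory column is missing from the input table."""


class CohortValidationError(ValueError):
    """One or more rows violate the data contract.

    Carries ``problems``: a list of ``(line_number, message)`` pairs
    (1-based line numbers including the header line).
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.problems[:10])
        more = "" if len(self.problems) <= 10 else f" (+{len(self.problems) - 10} more)"
        super().__init__(f"{len(self.problems)} malformed row(s): {lines}{more}")


class EmptyCohortError(ValueError):
    """No subjects remain after exclusion filtering."""


@dataclass(frozen=True)
class Observation:
    time: float  # days since baseline, >= 0
    kind: str  # "appetite" | "weight"
    value: float  # mm in [0, 100] for appetite; kg > 0 for weight

    def __post_init__(self):
        if self.kind not in OBS_KINDS:
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"time must be finite and >= 0, got {self.time}")
        if not math.isfinite(self.value):
            raise ValueError("observation value must be finite")
        if self.kind == APPETITE and not (0.0 <= self.value <= 100.0):
            raise ValueError(f"appetite score {self.value} outside [0, 100] mm")
        if self.kind == WEIGHT and self.value <= 0:
            raise ValueError(f"weight {self.value} must be > 0 kg")


@dataclass(frozen=True)
class SurvivalOutcome:
    time_months: float  # > 0 (a floor is applied by generators at 0)
    event: bool  # True = death observed, False = censored

    def __post_init__(self):
        if not math.isfinite(self.time_months) or self.time_months < 0:
            raise ValueError(f"survival time must be finite and >= 0, got {self.time_months}")

    @property
    def time_days(self) -> float:
        return self.time_months * MONTH_DAYS


@dataclass(frozen=True)
class Covariates:
    """Baseline covariates; any entry may be absent (None).

    Subjects with a missing covariate are retained for model fitting and
    only dropped from analyses that use that covariate (no imputation).
    """

    sex: Optional[str] = None
    ecog: Optional[int] = None
    smoking: Optional[str] = None
    age: Optional[float] = None

    def __post_init__(self):
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.ecog is not None and int(self.ecog) not in ECOG_LEVELS:
            raise ValueError(f"ECOG must be in {ECOG_LEVELS}, got {self.ecog}")
        if self.smoking is not None and self.smoking not in SMOKING:
            raise ValueError(f"smoking must be one of {SMOKING}, got {self.smoking!r}")
        if self.age is not None and not (18.0 <= self.age <= 110.0):
            raise ValueError(f"age must be in [18, 110], got {self.age}")


@dataclass
class SubjectRecord:
    subject_id: str
    covariates: Covariates = field(default_factory=Covariates)
    observations: list[Observation] = field(default_factory=list)
    survival: Optional[SurvivalOutcome] = None

    def __post_init__(self):
        self.observations = sorted(self.observations, key=lambda o: (o.time, o.kind))

    def observations_of(self, kind: str) -> list[Observation]:
        return [o for o in self.observations if o.kind == kind]

    def times_values(self, kind: str) -> tuple[np.ndarray, np.ndarray]:
        obs = self.observations_of(kind)
        return (np.array([o.time for o in obs]), np.array([o.value for o in obs]))

    def n_observations(self, kind: str) -> int:
        return sum(1 for o in self.observations if o.kind == kind)


@dataclass
class CohortDataset:
    label: str  # "recovering" | "chemotherapy" | "custom"
    subjects: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


@dataclass
class ExclusionReport:
    n_before: int
    n_after: int
    excluded: list[dict] = field(default_factory=list)  # {"subject_id", "reason"}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def apply_exclusions(cohort: CohortDataset) -> tuple[CohortDataset, ExclusionReport]:
    """Remove subjects with fewer than two appetite or two weight measurements.

    No imputation is performed; mid-study missing visits are simply absent
    rows.  Raises :class:`EmptyCohortError` if nothing remains.
    Idempotent: applying twice equals applying once.
    """
    kept, excluded = [], []
    for s in cohort.subjects:
        n_app = s.n_observations(APPETITE)
        n_wt = s.n_observations(WEIGHT)
        if n_app < 2 or n_wt < 2:
            reasons = []
            if n_app < 2:
                reasons.append(f"only {n_app} appetite measurement(s)")
            if n_wt < 2:
                reasons.append(f"only {n_wt} weight measurement(s)")
            excluded.append({"subject_id": s.subject_id, "reason": "; ".join(reasons)})
        else:
            kept.append(s)
    if not kept:
        raise EmptyCohortError("no subjects remain after exclusion filtering")
    report = ExclusionReport(n_before=len(cohort), n_after=len(kept), excluded=excluded)
    return CohortDataset(label=cohort.label, subjects=kept), report


def _parse_optional(value, caster):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return caster(value)


def read_cohort(path, schema: Optional[dict] = None, label: str = "custom") -> CohortDataset:
    """Parse a long-format CSV into a :class:`CohortDataset`.

    ``schema`` maps the logical column names (``id``, ``time``, ``kind``,
    ``value`` and optionally ``sex``, ``ecog``, ``smoking``, ``age``,
    ``os_months``, ``os_event``) to the actual CSV headers; defaults to
    :data:`DEFAULT_SCHEMA`.  Malformed rows are reported with their
    1-based line numbers.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, dtype={cols["id"]: str})
    for logical in MANDATORY_COLUMNS:
        if cols[logical] not in df.columns:
            raise SchemaError(
                f"mandatory column {cols[logical]!r} (for {logical!r}) missing; "
                f"found {list(df.columns)}"
            )

    problems: list[tuple[int, str]] = []
    per_subject: dict[str, dict] = {}
    has = {k: cols[k] in df.columns for k in cols}

    for idx, row in df.iterrows():
        line = int(idx) + 2  # header occupies line 1
        sid = row[cols["id"]]
        try:
            obs = Observation(
                time=float(row[cols["time"]]),
                kind=str(row[cols["kind"]]).strip().lower(),
                value=float(row[cols["value"]]),
            )
        except (ValueError, TypeError) as exc:
            problems.append((line, f"subject {sid}, t={row[cols['time']]}: {exc}"))
            continue
        entry = per_subject.setdefault(sid, {"obs": [], "cov": None, "surv": None})
        entry["obs"].append(obs)
        if entry["cov"] is None:
            try:
                ecog = _parse_optional(row[cols["ecog"]], lambda v: int(float(v))) if has["ecog"] else None
                entry["cov"] = Covariates(
                    sex=_parse_optional(row[cols["sex"]], str) if has["sex"] else None,
                    ecog=ecog,
                    smoking=_parse_optional(row[cols["smoking"]], str) if has["smoking"] else None,
                    age=_parse_optional(row[cols["age"]], float) if has["age"] else None,
                )
            except ValueError as exc:
                problems.append((line, f"subject {sid}: {exc}"))
                entry["cov"] = Covariates()
        if entry["surv"] is None and has["os_months"]:
            months = _parse_optional(row[cols["os_months"]], float)
            if months is not None:
                ev = _parse_optional(row[cols["os_event"]], lambda v: bool(int(float(v)))) if has["os_event"] else False
                try:
                    entry["surv"] = SurvivalOutcome(time_months=months, event=bool(ev))
                except ValueError as exc:
                    problems.append((line, f"subject {sid}: {exc}"))

    if problems:
        raise CohortValidationError(problems)

    subjects = [
        SubjectRecord(subject_id=sid, covariates=e["cov"] or Covariates(),
                      observations=e["obs"], survival=e["surv"])
        for sid, e in per_subject.items()
    ]
    return CohortDataset(label=label, subjects=subjects)


def write_cohort(cohort: CohortDataset, path, schema: Optional[dict] = None) -> None:
    """Write a cohort in the same long CSV dialect that `read_cohort` accepts."""
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    rows = []
    for s in cohort.subjects:
        cov, surv = s.covariates, s.survival
        for o in s.observations:
            rows.append({
                cols["id"]: s.subject_id,
                cols["time"]: o.time,
                cols["kind"]: o.kind,
                cols["value"]: o.value,
                cols["sex"]: cov.sex,
                cols["ecog"]: cov.ecog,
                cols["smoking"]: cov.smoking,
                cols["age"]: cov.age,
                cols["os_months"]: None if surv is None else surv.time_months,
                cols["os_event"]: None if surv is None else int(surv.event),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def cohort_to_frame(cohort: CohortDataset) -> pd.DataFrame:
    """Long-format DataFrame view (internal convenience)."""
    rows = []
    for s in cohort.subjects:
        for o in s.observations:
            rows.append({"subject_id": s.subject_id, "time": o.time,
                         "kind": o.kind, "value": o.value})
    return pd.DataFrame(rows)
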