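"""NONMEM-style rectangular dataset IO and trough-structure validation.

The supported dialect covers what steady-state TDM data need: ``EVID=1``
rows are dose events (``SS=1`` with ``II`` marks steady-state dosing,
``ADDL`` expands additional implied doses), ``EVID=0``/``MDV=0`` rows are
observations, compartment 2 is the parent and 3 the metabolite.  Missing
cells are written as ``.`` as is customary for these files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseEvent",
    "Observation",
    "SubjectRecord",
    "Cohort",
    "read_dataset",
    "write_dataset",
    "validate_trough_structure",
    "LLOQ",
]

#: lower limit of quantification of the bioassay, ng/mL
LLOQ = 1.0

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "CMT", "EVID", "MDV")
COVARIATE_COLUMNS = ("SEX", "AGE", "WT")
CMT_TO_ANALYTE = {2: "parent", 3: "metabolite"}
ANALYTE_TO_CMT = {v: k for k, v in CMT_TO_ANALYTE.items()}


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class DoseEvent:
    amount: float          # mg
    time: float            # h
    interval: float = 24.0  # h (II)
    steady_state: bool = False
    addl: int = 0

    def __post_init__(self) -> None:
        if self.steady_state and self.interval <= 0:
            raise DatasetError("steady-state dose events require a positive interval")


@dataclass(frozen=True)
class Observation:
    time: float
    analyte: str
    value: float           # ng/mL
    below_lloq: bool = False


@dataclass
class SubjectRecord:
    subject_id: str
    dose_events: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    covariates: dict[str, float] = field(default_factory=dict)

    def usable_observations(self) -> list[Observation]:
        """Observations retained for fitting (BLQ excluded by default)."""
        return [o for o in self.observations if not o.below_lloq]


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DatasetError("subject ids are not unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def n_observations(self, analyte: str | None = None) -> int:
        return sum(
            1
            for s in self.subjects
            for o in s.observations
            if analyte is None or o.analyte == analyte
        )

    def sex_counts(self) -> dict[str, int]:
        female = sum(1 for s in self.subjects if s.covariates.get("SEX", 0) == 0)
        return {"female": female, "male": len(self.subjects) - female}


def _num(value, row: int, col: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise DatasetError(f"row {row}: non-numeric {col}={value!r}") from None


def read_dataset(path, lloq: float = LLOQ) -> Cohort:
    """Read a NONMEM-style CSV into a validated :class:`Cohort`."""
    df = pd.read_csv(path, na_values=["."], skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {', '.join(missing)}")

    subjects: list[SubjectRecord] = []
    for sid, g in df.groupby("ID", sort=False):
        rec = SubjectRecord(subject_id=str(sid))
        for col in COVARIATE_COLUMNS:
            if col in g.columns and not g[col].isna().all():
                rec.covariates[col] = float(g[col].dropna().iloc[0])
        last_t = -np.inf
        for idx, row in g.iterrows():
            t = _num(row["TIME"], idx, "TIME")
            if t < 0:
                raise DatasetError(f"row {idx}: negative TIME")
            if t < last_t:
                raise DatasetError(f"row {idx}: times not non-decreasing within subject {sid}")
            last_t = t
            evid = int(_num(row["EVID"], idx, "EVID"))
            if evid == 1:
                amt = _num(row["AMT"], idx, "AMT")
                ss_raw = row.get("SS", 0)
                ss = (not pd.isna(ss_raw)) and int(_num(ss_raw, idx, "SS")) == 1
                ii = row.get("II", np.nan)
                ii = float(ii) if not pd.isna(ii) else 24.0
                addl = row.get("ADDL", 0)
                addl = int(addl) if not pd.isna(addl) else 0
                rec.dose_events.append(
                    DoseEvent(amount=amt, time=t, interval=ii, steady_state=ss, addl=addl))
            elif evid == 0:
                mdv = int(_num(row["MDV"], idx, "MDV")) if not pd.isna(row["MDV"]) else 0
                if mdv != 0:
                    continue
                cmt = int(_num(row["CMT"], idx, "CMT"))
                if cmt not in CMT_TO_ANALYTE:
                    raise DatasetError(f"row {idx}: observation in unknown compartment {cmt}")
                dv = _num(row["DV"], idx, "DV")
                rec.observations.append(
                    Observation(time=t, analyte=CMT_TO_ANALYTE[cmt], value=dv,
                                below_lloq=dv < lloq))
            else:
                raise DatasetError(f"row {idx}: unsupported EVID {evid}")
        subjects.append(rec)
    return Cohort(subjects=subjects, provenance=str(path))


def write_dataset(cohort: Cohort, path) -> None:
    """Write a cohort back to the documented NONMEM-style CSV column set."""
    rows = []
    for s in cohort.subjects:
        cov = {c: s.covariates.get(c, np.nan) for c in COVARIATE_COLUMNS}
        events: list[tuple[float, int, dict]] = []
        for d in s.dose_events:
            events.append((d.time, 1, {
                "AMT": d.amount, "DV": np.nan, "CMT": 1, "EVID": 1, "MDV": 1,
                "SS": 1 if d.steady_state else 0, "II": d.interval, "ADDL": d.addl}))
        for o in s.observations:
            events.append((o.time, 0, {
                "AMT": np.nan, "DV": o.value, "CMT": ANALYTE_TO_CMT[o.analyte],
                "EVID": 0, "MDV": 0, "SS": 0, "II": np.nan, "ADDL": 0}))
        events.sort(key=lambda e: (e[0], -e[1]))
        for t, _, payload in events:
            rows.append({"ID": s.subject_id, "TIME": t, **payload, **cov})
    df = pd.DataFrame(rows, columns=["ID", "TIME", "AMT", "DV", "CMT", "EVID",
                                     "MDV", "SS", "II", "ADDL", *COVARIATE_COLUMNS])
    df.to_csv(path, index=False, na_rep=".")


def validate_trough_structure(cohort: Cohort, rtol: float = 1e-6) -> list[dict]:
    """Report observations that are not steady-state troughs.

    A conforming observation sits exactly ``k * II`` hours (integer k >= 1)
    after a steady-state dose event of its subject.  Returns one violation
    dict per offending observation (empty list for conforming cohorts).
    """
    violations: list[dict] = []
    for s in cohort.subjects:
        ss_doses = [d for d in s.dose_events if d.steady_state]
        for o in s.observations:
            if not s.dose_events:
                violations.append({"subject_id": s.subject_id, "time": o.time,
                                   "reason": "observation without any dose event"})
                continue
            ok = False
            for d in ss_doses:
                if o.time <= d.time:
                    continue
                k = (o.time - d.time) / d.interval
                if abs(k - round(k)) <= rtol * max(1.0, k) and round(k) >= 1:
                    ok = True
                    break
            if not ok:
                reason = ("observation at mid-interval" if ss_doses
                          else "observation without a steady-state dose")
                violations.append({"subject_id": s.subject_id, "time": o.time,
                                   "reason": reason})
    return violations
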