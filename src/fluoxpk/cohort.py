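"""Synthetic trough-only TDM cohorts with the study population's structure.

The generator emulates the external-evaluation dataset the analyses assume:
198 psychiatric patients (146 female / 52 male), once-daily oral dosing of
20--60 mg, steady-state trough sampling only, paired parent and metabolite
concentrations at each sampling time, and an assay LLOQ of 1 ng/mL.  Ages
come from a pediatric/adult mixture (12--17 median 15; 18--56 median 21,
mixed 102:92) and weights from a truncated log-normal (median 59 kg,
range 35.9--115 kg).  Sex counts are exact by construction; everything
else is sampled, fully determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from . import pk
from .dataset import LLOQ, Cohort, DoseEvent, Observation, SubjectRecord
from .models import ModelSpec, builtin_model, individual_parameters

__all__ = ["CohortDesign", "generate_cohort", "cohort_summary"]

#: log-normal sigma for body weight, fitted so the 0.1/99.9 percentiles span
#: the observed 35.9--115 kg range around the 59 kg median
_WT_SIGMA = (math.log(115.0) - math.log(35.9)) / (2 * 3.0902)


@dataclass(frozen=True)
class CohortDesign:
    """Everything that determines one synthetic cohort (given a seed)."""

    n_subjects: int = 198
    male_fraction: float = 52 / 198
    pediatric_fraction: float = 102 / 194
    age_pediatric_range: tuple[int, int] = (12, 17)
    age_adult_range: tuple[int, int] = (18, 56)
    weight_median: float = 59.0
    weight_range: tuple[float, float] = (35.9, 115.0)
    dose_levels: Mapping[float, float] = field(
        default_factory=lambda: {20.0: 0.4, 40.0: 0.4, 60.0: 0.2})
    obs_per_subject: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.78, 2: 0.22})
    interval_tau: float = 24.0
    generating_model: ModelSpec | str = "FINAL"
    include_iiv: bool = True
    include_residual: bool = True
    lloq: float = LLOQ
    seed: int = 0

    def __post_init__(self) -> None:
        for probs, label in ((self.dose_levels, "dose_levels"),
                             (self.obs_per_subject, "obs_per_subject")):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label} probabilities sum to {total}, not 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        lo, hi = self.weight_range
        if not (0 < lo < self.weight_median < hi):
            raise ValueError("weight_range must bracket the median")

    @property
    def model(self) -> ModelSpec:
        if isinstance(self.generating_model, str):
            return builtin_model(self.generating_model)
        return self.generating_model

    @classmethod
    def from_yaml(cls, source) -> "CohortDesign":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        if "dose_levels" in d:
            d["dose_levels"] = {float(k): float(v) for k, v in d["dose_levels"].items()}
        if "obs_per_subject" in d:
            d["obs_per_subject"] = {int(k): float(v) for k, v in d["obs_per_subject"].items()}
        for key in ("age_pediatric_range", "age_adult_range", "weight_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _sample_ages(rng: np.random.Generator, design: CohortDesign, n: int) -> np.ndarray:
    pediatric = rng.random(n) < design.pediatric_fraction
    lo_p, hi_p = design.age_pediatric_range
    lo_a, hi_a = design.age_adult_range
    ages = rng.integers(lo_p, hi_p + 1, size=n).astype(float)
    # adults: right-skewed about the observed median of 21 y, truncated at 56
    adult = np.exp(rng.normal(math.log(lo_a + 3 - 17.0), 0.8, size=n)) + 17.0
    adult = np.clip(np.round(adult), lo_a, hi_a)
    return np.where(pediatric, ages, adult)


def _sample_weights(rng: np.random.Generator, design: CohortDesign, n: int) -> np.ndarray:
    lo, hi = design.weight_range
    wt = np.exp(rng.normal(math.log(design.weight_median), _WT_SIGMA, size=n))
    # redraw out-of-range values (truncation, not clipping, keeps the shape)
    bad = (wt < lo) | (wt > hi)
    while bad.any():
        wt[bad] = np.exp(rng.normal(math.log(design.weight_median), _WT_SIGMA, size=int(bad.sum())))
        bad = (wt < lo) | (wt > hi)
    return np.round(wt, 1)


def generate_cohort(design: CohortDesign) -> Cohort:
    """Draw one cohort: covariates, doses, etas, noisy paired troughs."""
    rng = np.random.default_rng(design.seed)
    spec = design.model
    n = design.n_subjects

    n_male = round(n * design.male_fraction)
    sexes = rng.permutation(np.r_[np.ones(n_male), np.zeros(n - n_male)])
    ages = _sample_ages(rng, design, n)
    weights = _sample_weights(rng, design, n)
    doses = rng.choice(list(design.dose_levels), size=n, p=list(design.dose_levels.values()))
    n_obs = rng.choice(list(design.obs_per_subject), size=n,
                       p=list(design.obs_per_subject.values()))

    subjects: list[SubjectRecord] = []
    tau = design.interval_tau
    for i in range(n):
        cov = {"SEX": float(sexes[i]), "AGE": float(ages[i]), "WT": float(weights[i])}
        eta = {}
        if design.include_iiv:
            for key in spec.iiv_keys:
                eta[key] = rng.normal(0.0, spec.random_effects.omega(key))
        params = individual_parameters(spec, cov, eta)
        regimen = pk.DosingRegimen(dose_amount=float(doses[i]), interval_tau=tau)
        trough = pk.steady_state_trough(params, regimen)

        rec = SubjectRecord(subject_id=f"{i + 1}", covariates=cov)
        rec.dose_events.append(DoseEvent(amount=float(doses[i]), time=0.0,
                                         interval=tau, steady_state=True))
        for k in range(int(n_obs[i])):
            t = tau * (k + 1)
            for analyte in spec.analytes:
                f = trough[analyte]
                y = f
                if design.include_residual:
                    prop_sd, add_sd = spec.random_effects.sigma(analyte)
                    y = f * (1.0 + rng.normal(0.0, prop_sd)) + rng.normal(0.0, add_sd)
                y = max(y, 0.0)
                rec.observations.append(
                    Observation(time=t, analyte=analyte, value=y,
                                below_lloq=y < design.lloq))
        subjects.append(rec)
    return Cohort(subjects=subjects,
                  provenance=f"synthetic:{spec.name}:seed={design.seed}")


def cohort_summary(cohort: Cohort) -> dict:
    """Descriptive statistics mirroring the study's cohort table."""
    if not cohort.subjects:
        raise ValueError("empty cohort")

    def med_range(values):
        a = np.asarray(values, dtype=float)
        return {"median": float(np.median(a)), "min": float(a.min()), "max": float(a.max())}

    ages = [s.covariates["AGE"] for s in cohort.subjects if "AGE" in s.covariates]
    weights = [s.covariates["WT"] for s in cohort.subjects if "WT" in s.covariates]
    out = {
        "n_subjects": len(cohort),
        **cohort.sex_counts(),
        "age": med_range(ages) if ages else None,
        "weight": med_range(weights) if weights else None,
        "observations": {},
    }
    for analyte in ("parent", "metabolite"):
        values = [o.value for s in cohort.subjects for o in s.observations
                  if o.analyte == analyte]
        if values:
            out["observations"][analyte] = {"n": len(values), **med_range(values)}
    return out
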