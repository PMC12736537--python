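"""External-evaluation metrics and simulation-based diagnostics.

Prediction error is relative and signed, PE = (pred - obs)/obs, reported in
percent; MPE is its mean and RMSE the root of the mean squared PE, so that
RMSE^2 = MPE^2 + Var(PE) holds as an exact (population-variance) identity.
NPDE follows the standard decorrelation construction: per subject, the
observed vector is standardized by the empirical mean and lower Cholesky
factor of its simulated distribution, ranked against the equally
standardized simulations (mid-rank, clamped), and mapped through the
standard-normal quantile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular

from .dataset import Cohort, SubjectRecord
from .estimation import EstimationError, EtaVector, _Conditional, _Design, map_estimate
from .models import ModelSpec

__all__ = [
    "EvaluationReport",
    "VPCResult",
    "prediction_errors",
    "external_evaluate",
    "npde",
    "cwres",
    "vpc",
]


@dataclass
class EvaluationReport:
    pe: dict[str, dict[str, float]]          # level ("pred"/"ipred") -> metrics (%)
    pe_vectors: dict[str, np.ndarray]        # per-observation PE (fractions)
    gof: pd.DataFrame                        # obs, PRED, IPRED, CWRES, time, analyte
    n_excluded: int = 0
    npde_values: np.ndarray | None = None
    npde_tests: dict[str, float] | None = None


@dataclass
class VPCResult:
    bins: list
    observed: pd.DataFrame        # bin, percentile, value
    simulated_ci: pd.DataFrame    # bin, percentile, lo, hi
    prediction_corrected: bool
    per_observation: pd.DataFrame | None = None  # bin, dose, time, value


def prediction_errors(obs: Sequence[float], pred: Sequence[float]):
    """PE vector plus median PE, MPE and RMSE, all in percent.

    Observations <= 0 are excluded (PE is undefined there); the metrics
    dict carries the exclusion count.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    keep = obs > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} observation(s) with non-positive value")
    pe = (pred[keep] - obs[keep]) / obs[keep]
    if pe.size == 0:
        raise ValueError("no usable observations")
    metrics = {
        "median_pe": float(np.median(pe) * 100.0),
        "mpe": float(np.mean(pe) * 100.0),
        "rmse": float(math.sqrt(np.mean(pe ** 2)) * 100.0),
        "n": int(pe.size),
        "n_excluded": n_excluded,
    }
    return pe, metrics


def _cohort_design(spec: ModelSpec, cohort: Cohort) -> _Design:
    try:
        return _Design(spec, cohort)
    except EstimationError as exc:
        raise ValueError(str(exc)) from None


def external_evaluate(spec: ModelSpec, cohort: Cohort,
                      with_npde: bool = False, n_sim: int = 1000,
                      seed: int = 0) -> EvaluationReport:
    """Evaluate a published model against an independent cohort.

    PRED is the population prediction (eta = 0), IPRED the MAP-conditional
    prediction.  Only analytes the model describes are used (parent-only
    models are scored on parent observations).  Missing model covariates
    fall back to the substitution defaults carried by the ModelSpec.
    """
    rows = []
    for s in cohort.subjects:
        usable = [o for o in s.usable_observations() if o.analyte in spec.analytes]
        if not usable:
            continue
        from .estimation import individual_predictions

        eta = map_estimate(spec, s)
        tab = individual_predictions(spec, s, eta)
        tab["subject_id"] = s.subject_id
        tab["cwres"] = cwres(spec, s, eta=eta)
        rows.append(tab)
    if not rows:
        raise ValueError(
            f"no overlapping analytes between cohort and model {spec.name!r}")
    gof = pd.concat(rows, ignore_index=True)

    pe_metrics, pe_vectors = {}, {}
    for level, col in (("pred", "pred"), ("ipred", "ipred")):
        vec, metrics = prediction_errors(gof["obs"].to_numpy(), gof[col].to_numpy())
        pe_metrics[level] = metrics
        pe_vectors[level] = vec

    report = EvaluationReport(pe=pe_metrics, pe_vectors=pe_vectors, gof=gof,
                              n_excluded=pe_metrics["pred"]["n_excluded"])
    if with_npde:
        values, tests = npde(spec, cohort, n_sim=n_sim, seed=seed)
        report.npde_values = values
        report.npde_tests = tests
    return report


def _simulate_observation_matrix(design: _Design, spec: ModelSpec, n_sim: int,
                                 rng: np.random.Generator,
                                 include_residual: bool = True) -> np.ndarray:
    """(n_sim, n_obs) matrix of model-simulated replicate observations."""
    omega = np.array([spec.random_effects.omega(k) for k in design.iiv_keys])
    tv = dict(spec.typical_values)
    thetas = [e.theta for e in design.effects]
    prop_sd = np.where(design.obs_metab, spec.random_effects.sigma("metabolite")[0]
                       if "metabolite" in spec.analytes else 0.0,
                       spec.random_effects.sigma("parent")[0])
    add_sd = np.where(design.obs_metab, spec.random_effects.sigma("metabolite")[1]
                      if "metabolite" in spec.analytes else 0.0,
                      spec.random_effects.sigma("parent")[1])
    out = np.empty((n_sim, design.n_obs))
    for r in range(n_sim):
        eta = rng.normal(0.0, omega, size=(design.n_subjects, len(omega)))
        f = design.predict(design.subject_values(tv, thetas, eta))
        if include_residual:
            y = f * (1.0 + rng.normal(0.0, 1.0, f.shape) * prop_sd) \
                + rng.normal(0.0, 1.0, f.shape) * add_sd
        else:
            y = f
        out[r] = np.maximum(y, 0.0)
    return out


def npde(spec: ModelSpec, cohort: Cohort, n_sim: int = 1000, seed: int = 0,
         ridge: float = 1e-10):
    """Normalized prediction distribution errors with the three null tests.

    Returns ``(npde_values, tests)`` where ``tests`` maps ``wilcoxon``
    (H0: location 0), ``fisher_variance`` (H0: variance 1) and
    ``shapiro`` (H0: normal) to their p-values on the pooled vector.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    design = _cohort_design(spec, cohort)
    rng = np.random.default_rng(seed)
    sims = _simulate_observation_matrix(design, spec, n_sim, rng)

    values = np.empty(design.n_obs)
    lo = 1.0 / (2.0 * n_sim)
    for i in range(design.n_subjects):
        idx = np.flatnonzero(design.obs_subj == i)
        if idx.size == 0:
            continue
        y = design.obs_y[idx]
        S = sims[:, idx]
        m = S.mean(axis=0)
        V = np.cov(S, rowvar=False, ddof=1).reshape(idx.size, idx.size)
        try:
            L = cholesky(V, lower=True)
        except np.linalg.LinAlgError:
            warnings.warn("singular simulated covariance; ridge-regularized")
            L = cholesky(V + ridge * np.eye(idx.size) * max(1.0, np.trace(V)),
                         lower=True)
        y_star = solve_triangular(L, y - m, lower=True)
        s_star = solve_triangular(L, (S - m).T, lower=True).T
        # mid-rank of each decorrelated observation among its simulations
        less = (s_star < y_star).sum(axis=0)
        equal = (s_star == y_star).sum(axis=0)
        pde = (less + 0.5 * equal) / n_sim
        values[idx] = stats.norm.ppf(np.clip(pde, lo, 1.0 - lo))

    n = values.size
    wilcoxon_p = float(stats.wilcoxon(values, zero_method="wilcox").pvalue)
    var_stat = (n - 1) * float(np.var(values, ddof=1))
    fisher_p = float(2.0 * min(stats.chi2.cdf(var_stat, n - 1),
                               stats.chi2.sf(var_stat, n - 1)))
    shapiro_p = float(stats.shapiro(values).pvalue)
    tests = {"wilcoxon": wilcoxon_p, "fisher_variance": fisher_p,
             "shapiro": shapiro_p}
    return values, tests


def cwres(spec: ModelSpec, subject: SubjectRecord,
          eta: EtaVector | None = None, ridge: float = 1e-10) -> np.ndarray:
    """Conditional weighted residuals (FOCE linearization) for one subject.

    The residual about the linearized conditional expectation is whitened by
    the lower Cholesky factor of the linearized marginal covariance
    G Omega G' + diag(g); under the true model the pooled values have mean
    ~0 and SD ~1.
    """
    from .estimation import _FD_ETA, _single_subject_design

    if eta is None:
        eta = map_estimate(spec, subject)
    d = _single_subject_design(spec, subject)
    omega = np.array([spec.random_effects.omega(k) for k in d.iiv_keys])
    cond = _Conditional(d, dict(spec.typical_values), [e.theta for e in d.effects],
                        omega, {a: spec.random_effects.sigma(a) for a in spec.analytes})
    eta_arr = np.array([[eta.values.get(k, 0.0) for k in d.iiv_keys]])
    f0 = cond.f(eta_arr)
    g = (cond.sig_prop * f0) ** 2 + cond.sig_add ** 2
    act = np.flatnonzero(omega > 0)
    if act.size:
        G = np.empty((d.n_obs, act.size))
        for a, k in enumerate(act):
            ep = eta_arr.copy(); ep[0, k] += _FD_ETA
            em = eta_arr.copy(); em[0, k] -= _FD_ETA
            G[:, a] = (cond.f(ep) - cond.f(em)) / (2 * _FD_ETA)
        C = G @ np.diag(omega[act] ** 2) @ G.T + np.diag(g)
        r = d.obs_y - (f0 - G @ eta_arr[0, act])
    else:
        C = np.diag(g)
        r = d.obs_y - f0
    try:
        L = cholesky(C, lower=True)
    except np.linalg.LinAlgError:
        warnings.warn("non-PD linearized covariance; ridge-regularized")
        L = cholesky(C + ridge * np.trace(C) * np.eye(len(r)), lower=True)
    return solve_triangular(L, r, lower=True)


def vpc(spec: ModelSpec, cohort: Cohort, n_sim: int = 200,
        binning: str = "dose", prediction_corrected: bool = False,
        seed: int = 0, percentiles=(5.0, 50.0, 95.0),
        min_bin_size: int = 5) -> VPCResult:
    """Visual-predictive-check percentiles with simulated confidence bands.

    Bins observations by dose level (default, the natural axis for
    trough-only data) or by time; within each bin the observed 5/50/95th
    percentiles are compared with the 2.5--97.5% envelope of the same
    percentiles across ``n_sim`` simulated replicate cohorts.  With
    ``prediction_corrected`` every value is rescaled by
    median(PRED in bin)/PRED of its subject.
    """
    if n_sim < 200:
        raise ValueError("n_sim must be >= 200")
    design = _cohort_design(spec, cohort)
    rng = np.random.default_rng(seed)

    dose_per_obs = np.zeros(design.n_obs)
    np.maximum.at(dose_per_obs, design.term_obs, design.term_dose)
    if binning == "dose":
        axis = dose_per_obs
    elif binning == "time":
        axis = design.obs_time
    else:
        raise ValueError(f"unknown binning {binning!r}")

    levels = sorted(set(axis.tolist()))
    # merge undersized bins with their left neighbour
    bins: list[list[float]] = []
    for lv in levels:
        count = int((axis == lv).sum())
        if bins and count < min_bin_size:
            bins[-1].append(lv)
        else:
            bins.append([lv])
    bin_of_obs = np.zeros(design.n_obs, dtype=int)
    for b, members in enumerate(bins):
        bin_of_obs[np.isin(axis, members)] = b

    pred = design.predict(design.subject_values(
        dict(spec.typical_values), [e.theta for e in design.effects],
        np.zeros((design.n_subjects, len(design.iiv_keys)))))
    correction = np.ones(design.n_obs)
    if prediction_corrected:
        for b in range(len(bins)):
            sel = bin_of_obs == b
            correction[sel] = np.median(pred[sel]) / pred[sel]

    sims = _simulate_observation_matrix(design, spec, n_sim, rng) * correction
    obs = design.obs_y * correction

    obs_rows, ci_rows = [], []
    for b, members in enumerate(bins):
        sel = bin_of_obs == b
        label = members[0] if len(members) == 1 else tuple(members)
        for p in percentiles:
            obs_rows.append({"bin": label, "percentile": p,
                             "value": float(np.percentile(obs[sel], p))})
            sim_p = np.percentile(sims[:, sel], p, axis=1)
            ci_rows.append({"bin": label, "percentile": p,
                            "lo": float(np.percentile(sim_p, 2.5)),
                            "hi": float(np.percentile(sim_p, 97.5))})
    per_obs = pd.DataFrame({"bin": bin_of_obs, "dose": dose_per_obs,
                            "time": design.obs_time, "value": obs})
    return VPCResult(bins=[m[0] if len(m) == 1 else tuple(m) for m in bins],
                     observed=pd.DataFrame(obs_rows),
                     simulated_ci=pd.DataFrame(ci_rows),
                     prediction_corrected=prediction_corrected,
                     per_observation=per_obs)
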