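"""Structural pharmacokinetic computation.

One-compartment oral absorption for the parent drug (fluoxetine) and the
catenary parent->metabolite extension (norfluoxetine), with closed-form
multiple-dose superposition and a numerically integrated ODE fallback that
also serves as a brute-force oracle.

Conventions: doses in mg, volumes in L, clearances in L/h, rate constants
in 1/h.  Concentrations are mg/L internally and converted to ng/mL (x1000)
at the public boundary.  All parameters are apparent (CL/F, V/F); oral
bioavailability F is not separable from trough-only data and is fixed at 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PKParameters",
    "DosingRegimen",
    "ConcentrationPoint",
    "parent_conc",
    "metabolite_conc",
    "ode_profile",
    "steady_state_trough",
    "parent_conc_array",
    "metabolite_conc_array",
]

MG_L_TO_NG_ML = 1000.0

#: relative eigenvalue gap below which the analytic multi-exponential form is
#: abandoned (scalar API: ODE fallback; array API: minimal nudge apart)
EIGENVALUE_RTOL = 1e-6


class ParameterDomainError(ValueError):
    """A PK parameter is outside its physical domain."""


class IntegrationFailure(RuntimeError):
    """The ODE fallback failed to integrate; parameters are echoed."""


@dataclass(frozen=True)
class PKParameters:
    """Apparent individual (or typical) PK parameters of the joint model.

    ``cl_metab``/``v_metab`` may be omitted for parent-only models; ``mpr``
    (milk-to-plasma ratio) is only meaningful for models carrying a milk
    scaling factor.
    """

    cl_parent: float
    v_parent: float
    ka: float
    cl_metab: float | None = None
    v_metab: float | None = None
    fm: float = 1.0
    mpr: float | None = None

    def __post_init__(self) -> None:
        for name in ("cl_parent", "v_parent", "ka"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterDomainError(f"{name} must be strictly positive, got {v!r}")
        if (self.cl_metab is None) != (self.v_metab is None):
            raise ParameterDomainError("cl_metab and v_metab must be given together")
        if self.cl_metab is not None:
            for name in ("cl_metab", "v_metab"):
                v = getattr(self, name)
                if not (np.isfinite(v) and v > 0):
                    raise ParameterDomainError(f"{name} must be strictly positive, got {v!r}")
        if not (0.0 < self.fm <= 1.0):
            raise ParameterDomainError(f"fm must lie in (0, 1], got {self.fm!r}")
        if self.mpr is not None and self.mpr <= 0:
            raise ParameterDomainError(f"mpr must be strictly positive, got {self.mpr!r}")

    @property
    def ke(self) -> float:
        """Parent elimination rate constant CL_P/V_P, 1/h."""
        return self.cl_parent / self.v_parent

    @property
    def km(self) -> float:
        """Metabolite elimination rate constant CL_M/V_M, 1/h."""
        if self.cl_metab is None:
            raise ParameterDomainError("model has no metabolite disposition parameters")
        return self.cl_metab / self.v_metab

    @property
    def has_metabolite(self) -> bool:
        return self.cl_metab is not None

    def half_lives(self) -> dict[str, float]:
        out = {"absorption": math.log(2) / self.ka, "parent": math.log(2) / self.ke}
        if self.has_metabolite:
            out["metabolite"] = math.log(2) / self.km
        return out


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated oral dosing: ``n_doses=None`` means the steady-state limit."""

    dose_amount: float
    interval_tau: float = 24.0
    n_doses: int | None = None
    route: Literal["oral_first_order"] = "oral_first_order"

    def __post_init__(self) -> None:
        if self.dose_amount < 0:
            raise ParameterDomainError("dose_amount must be non-negative")
        if self.interval_tau <= 0:
            raise ParameterDomainError("interval_tau must be strictly positive")
        if self.n_doses is not None and self.n_doses < 1:
            raise ParameterDomainError("n_doses must be >= 1 (or None for steady state)")

    @property
    def steady_state(self) -> bool:
        return self.n_doses is None


@dataclass(frozen=True)
class ConcentrationPoint:
    time: float
    analyte: Literal["parent", "metabolite", "active_moiety"]
    value: float


# ---------------------------------------------------------------------------
# vectorised closed forms (arrays broadcast; used by simulation/estimation)
# ---------------------------------------------------------------------------


def _accum(lam, tau, n):
    """Superposition accumulation factor sum_{i<n} exp(-lam*i*tau).

    ``n`` may be ``np.inf`` for the steady-state limit (geometric series).
    """
    return -np.expm1(-n * lam * tau) / (-np.expm1(-lam * tau))


def _separate(*lams, rtol=EIGENVALUE_RTOL):
    """Nudge near-equal rate constants apart so the analytic form stays finite.

    The relative perturbation is O(rtol) and the induced concentration error
    is far below the 1e-4 closed-form/ODE agreement tolerance.
    """
    out = [np.asarray(l, dtype=float).copy() for l in lams]
    for i in range(1, len(out)):
        for j in range(i):
            scale = np.maximum(np.abs(out[i]), np.abs(out[j]))
            close = np.abs(out[i] - out[j]) < rtol * scale
            out[i] = np.where(close, out[i] * (1.0 + 3.0 * rtol * (i + 1)), out[i])
    return out


def parent_conc_array(t, dose, tau, cl, v, ka, n_doses=np.inf):
    """Parent concentration (ng/mL) at time ``t`` h after the last dose.

    All arguments broadcast; ``n_doses=np.inf`` gives the steady-state
    superposition limit.  Near ka==kE the elimination constant is nudged by
    ~3e-6 relative (negligible against any practical tolerance).
    """
    t, dose, tau, cl, v, ka, n = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (t, dose, tau, cl, v, ka, n_doses))
    )
    ke = cl / v
    ka_s, ke_s = _separate(ka, ke)
    coef = dose * ka_s / (v * (ka_s - ke_s))
    c = coef * (np.exp(-ke_s * t) * _accum(ke_s, tau, n) - np.exp(-ka_s * t) * _accum(ka_s, tau, n))
    return np.maximum(c, 0.0) * MG_L_TO_NG_ML


def metabolite_conc_array(t, dose, tau, cl_p, v_p, ka, cl_m, v_m, fm=1.0, n_doses=np.inf):
    """Metabolite concentration (ng/mL), tri-exponential superposition form."""
    t, dose, tau, cl_p, v_p, ka, cl_m, v_m, fm, n = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (t, dose, tau, cl_p, v_p, ka, cl_m, v_m, fm, n_doses))
    )
    ke = cl_p / v_p
    km = cl_m / v_m
    lams = _separate(ka, ke, km)
    coef = fm * dose * lams[0] * lams[1] / v_m
    total = np.zeros_like(coef)
    for i, lam in enumerate(lams):
        denom = np.ones_like(lam)
        for j, mu in enumerate(lams):
            if j != i:
                denom = denom * (mu - lam)
        total = total + np.exp(-lam * t) * _accum(lam, tau, n) / denom
    return np.maximum(coef * total, 0.0) * MG_L_TO_NG_ML


# ---------------------------------------------------------------------------
# scalar public API with ODE fallback on eigenvalue collision
# ---------------------------------------------------------------------------


def _check_t(t: float, regimen: DosingRegimen) -> None:
    if not (0.0 <= t <= regimen.interval_tau):
        raise ValueError(
            f"t must lie within the dosing interval [0, {regimen.interval_tau}], got {t}"
        )


def _collision(*lams, rtol=EIGENVALUE_RTOL) -> bool:
    lams = sorted(lams)
    return any(
        (b - a) < rtol * max(abs(a), abs(b)) for a, b in zip(lams, lams[1:])
    )


def parent_conc(params: PKParameters, regimen: DosingRegimen, t: float) -> float:
    """Parent trough-interval concentration, ng/mL, at ``t`` h after the last dose."""
    _check_t(t, regimen)
    if regimen.dose_amount == 0:
        return 0.0
    if _collision(params.ka, params.ke):
        return _ode_fallback(params, regimen, t, "parent")
    n = np.inf if regimen.steady_state else regimen.n_doses
    return float(
        parent_conc_array(t, regimen.dose_amount, regimen.interval_tau,
                          params.cl_parent, params.v_parent, params.ka, n)
    )


def metabolite_conc(params: PKParameters, regimen: DosingRegimen, t: float) -> float:
    """Metabolite concentration, ng/mL, at ``t`` h after the last dose."""
    _check_t(t, regimen)
    if not params.has_metabolite:
        raise ParameterDomainError("model has no metabolite disposition parameters")
    if regimen.dose_amount == 0 or params.fm == 0:
        return 0.0
    if _collision(params.ka, params.ke, params.km):
        return _ode_fallback(params, regimen, t, "metabolite")
    n = np.inf if regimen.steady_state else regimen.n_doses
    return float(
        metabolite_conc_array(t, regimen.dose_amount, regimen.interval_tau,
                              params.cl_parent, params.v_parent, params.ka,
                              params.cl_metab, params.v_metab, params.fm, n)
    )


def _rhs(params: PKParameters):
    ke = params.ke
    km = params.km if params.has_metabolite else 0.0
    fm = params.fm
    ka = params.ka

    def rhs(t, y):
        a, p, m = y
        return (-ka * a, ka * a - ke * p, fm * ke * p - km * m)

    return rhs


def _n_doses_to_ss(params: PKParameters, tau: float, decay: float = 1e-12) -> int:
    """Doses needed until the slowest exponential has decayed below ``decay``."""
    rates = [params.ka, params.ke]
    if params.has_metabolite:
        rates.append(params.km)
    n = math.ceil(-math.log(decay) / (min(rates) * tau))
    return max(n, 2)


def _integrate(params: PKParameters, dose: float, tau: float, n_doses: int,
               t_eval_last: Sequence[float]) -> np.ndarray:
    """Integrate n_doses QD-style doses; return states at ``t_eval_last`` after the last dose."""
    rhs = _rhs(params)
    y = np.zeros(3)
    for i in range(n_doses - 1):
        y[0] += dose
        sol = solve_ivp(rhs, (0.0, tau), y, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:  # pragma: no cover - LSODA is robust on linear systems
            raise IntegrationFailure(f"ODE integration failed for {params!r}")
        y = sol.y[:, -1]
    y[0] += dose
    t_eval = np.asarray(t_eval_last, dtype=float)
    t_span = (0.0, max(float(t_eval[-1]), tau))
    sol = solve_ivp(rhs, t_span, y, method="LSODA", rtol=1e-10, atol=1e-12,
                    t_eval=np.unique(np.concatenate([[0.0], t_eval])))
    if not sol.success:  # pragma: no cover
        raise IntegrationFailure(f"ODE integration failed for {params!r}")
    idx = np.searchsorted(sol.t, t_eval)
    return sol.y[:, idx]


def _ode_fallback(params: PKParameters, regimen: DosingRegimen, t: float, analyte: str) -> float:
    n = regimen.n_doses or _n_doses_to_ss(params, regimen.interval_tau)
    states = _integrate(params, regimen.dose_amount, regimen.interval_tau, n, [t])
    if analyte == "parent":
        return float(states[1, 0] / params.v_parent) * MG_L_TO_NG_ML
    return float(states[2, 0] / params.v_metab) * MG_L_TO_NG_ML


def ode_profile(params: PKParameters, regimen: DosingRegimen,
                grid: Sequence[float]) -> list[ConcentrationPoint]:
    """Numerically integrated profile over ``grid`` (h since first dose).

    Serves as the brute-force oracle for the closed forms and as the fallback
    for degenerate (eigenvalue-collision) parameter sets.  Requires a finite
    ``n_doses`` regimen; grid times are absolute since the first dose.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0) or grid[0] < 0:
        raise ValueError("grid must be strictly increasing and non-negative")
    if regimen.steady_state:
        raise ValueError("ode_profile requires a finite n_doses regimen")
    if regimen.dose_amount == 0:
        return [ConcentrationPoint(float(t), "active_moiety", 0.0) for t in grid]

    tau = regimen.interval_tau
    rhs = _rhs(params)
    y = np.zeros(3)
    out_p = np.empty_like(grid)
    out_m = np.empty_like(grid)
    t0 = 0.0
    gi = 0
    for i in range(regimen.n_doses):
        y[0] += regimen.dose_amount
        seg_end = (i + 1) * tau if i + 1 < regimen.n_doses else max(grid[-1], t0 + tau)
        in_seg = grid[(grid >= t0) & (grid <= seg_end if i + 1 == regimen.n_doses else grid < seg_end)]
        t_eval = np.unique(np.concatenate([[t0], in_seg - 0.0, [seg_end]]))
        sol = solve_ivp(rhs, (t0, seg_end), y, method="LSODA", rtol=1e-10, atol=1e-13,
                        t_eval=t_eval)
        if not sol.success:  # pragma: no cover
            raise IntegrationFailure(f"ODE integration failed for {params!r}")
        for tg in in_seg:
            j = int(np.searchsorted(sol.t, tg))
            out_p[gi] = sol.y[1, j] / params.v_parent
            out_m[gi] = (sol.y[2, j] / params.v_metab) if params.has_metabolite else 0.0
            gi += 1
        y = sol.y[:, -1]
        t0 = seg_end
        if gi == grid.size:
            break

    points: list[ConcentrationPoint] = []
    for t, cp, cm in zip(grid, out_p, out_m):
        points.append(ConcentrationPoint(float(t), "parent", float(cp * MG_L_TO_NG_ML)))
        if params.has_metabolite:
            points.append(ConcentrationPoint(float(t), "metabolite", float(cm * MG_L_TO_NG_ML)))
    return points


def steady_state_trough(params: PKParameters, regimen: DosingRegimen) -> dict[str, float]:
    """Trough (t = tau-) concentrations under the regimen, ng/mL.

    Warns when a finite regimen is shorter than 5 of the longest half-life,
    i.e. when the printed value should not be read as a steady-state trough.
    """
    if regimen.n_doses is not None:
        horizon = regimen.n_doses * regimen.interval_tau
        t_half_max = max(params.half_lives().values())
        if horizon < 5.0 * t_half_max:
            warnings.warn(
                f"regimen spans {horizon:.0f} h < 5 half-lives ({5 * t_half_max:.0f} h); "
                "trough is not at steady state", stacklevel=2)
    parent = parent_conc(params, regimen, regimen.interval_tau)
    out = {"parent": parent}
    if params.has_metabolite:
        out["metabolite"] = metabolite_conc(params, regimen, regimen.interval_tau)
    else:
        out["metabolite"] = 0.0
    out["active_moiety"] = out["parent"] + out["metabolite"]
    return out
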