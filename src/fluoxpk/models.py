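"""Declarative repository of published fluoxetine population-PK models.

Three fully parameterized models ship with the package:

* ``M1`` — perinatal model: one-compartment parent with a milk-to-plasma
  scaling factor (CL/F 8.42 L/h, V/F 690 L, ka fixed 0.3 /h, MPR 0.59).
* ``M2`` — pediatric model: one-compartment parent with weight-linear
  CL/F (0.181 L/h/kg) and V/F (37.4 L/kg), ka fixed 0.666 /h.
* ``FINAL`` — the joint parent--metabolite model: two connected
  one-compartment models with a 16.5% male shift on parent clearance.

Printed between-subject %CV values are interpreted as the standard
deviation of the log-scale random effect, omega = CV/100 (the usual
pharmacometric reporting convention; the distinction is second order at
CV <= 52%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Any, Literal, Mapping

import yaml

from .pk import PKParameters

__all__ = [
    "RandomEffectsSpec",
    "CovariateEffect",
    "ModelSpec",
    "builtin_model",
    "individual_parameters",
    "milk_concentration",
    "BUILTIN_MODELS",
]

BUILTIN_MODELS = ("M1", "M2", "FINAL")

#: reference coding for the sex covariate throughout the package
FEMALE, MALE = 0, 1


class UnknownModelError(KeyError):
    pass


class MissingCovariateError(KeyError):
    pass


class UnsupportedStructureError(ValueError):
    pass


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Between-subject (IIV) and residual (RUV) variability magnitudes.

    ``iiv_sd`` maps a PK parameter name to the SD of its log-scale random
    effect; ``ruv_prop_sd`` / ``ruv_add_sd`` map an analyte name to the
    proportional (fraction) and additive (ng/mL) residual SDs of the
    combined error model y = f*(1+eps_p) + eps_a.
    """

    iiv_sd: Mapping[str, float] = field(default_factory=dict)
    ruv_prop_sd: Mapping[str, float] = field(default_factory=dict)
    ruv_add_sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.iiv_sd, self.ruv_prop_sd, self.ruv_add_sd):
            for k, v in m.items():
                if v < 0:
                    raise ValueError(f"negative SD for {k!r}: {v}")
        for analyte in set(self.ruv_prop_sd) | set(self.ruv_add_sd):
            if self.ruv_prop_sd.get(analyte, 0.0) == 0.0 and self.ruv_add_sd.get(analyte, 0.0) == 0.0:
                raise ValueError(f"analyte {analyte!r} has no nonzero residual component")

    def omega(self, parameter: str) -> float:
        return float(self.iiv_sd.get(parameter, 0.0))

    def sigma(self, analyte: str) -> tuple[float, float]:
        return (float(self.ruv_prop_sd.get(analyte, 0.0)),
                float(self.ruv_add_sd.get(analyte, 0.0)))


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relation.

    ``fractional_shift``: multiplicative factor (1 + theta)**x for a {0,1}
    coded covariate x (e.g. the 16.5% male shift on CL_P/F).
    ``linear``: factor x**theta for a strictly positive continuous covariate
    (theta=1 reproduces the printed weight-linear CL/F = 0.181 x BW form,
    with the typical value holding the per-unit slope).
    """

    parameter: str
    covariate: str
    form: Literal["fractional_shift", "linear"]
    theta: float

    def factor(self, value: float) -> float:
        if self.form == "fractional_shift":
            if value not in (0, 1):
                raise ValueError(
                    f"covariate {self.covariate!r} must be coded 0/1, got {value!r}")
            return (1.0 + self.theta) ** value
        if value <= 0:
            raise ValueError(
                f"covariate {self.covariate!r} must be strictly positive, got {value!r}")
        return float(value) ** self.theta


@dataclass(frozen=True)
class ModelSpec:
    """Structural + covariate + random-effects definition of one PopPK model."""

    name: str
    structure: Literal["parent_only", "parent_metabolite", "parent_milk"]
    typical_values: Mapping[str, float]
    fixed_parameters: frozenset = frozenset()
    covariate_effects: tuple[CovariateEffect, ...] = ()
    random_effects: RandomEffectsSpec = field(default_factory=RandomEffectsSpec)
    covariate_defaults: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.random_effects.iiv_sd:
            if key not in self.typical_values:
                raise ValueError(f"IIV key {key!r} names no model parameter")
        for eff in self.covariate_effects:
            if eff.parameter not in self.typical_values:
                raise ValueError(f"covariate effect targets unknown parameter {eff.parameter!r}")

    # -- analytes ----------------------------------------------------------
    @property
    def analytes(self) -> tuple[str, ...]:
        if self.structure == "parent_metabolite":
            return ("parent", "metabolite")
        return ("parent",)

    @property
    def iiv_keys(self) -> tuple[str, ...]:
        return tuple(self.random_effects.iiv_sd)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "structure": self.structure,
            "typical_values": dict(self.typical_values),
            "fixed_parameters": sorted(self.fixed_parameters),
            "covariate_effects": [
                {"parameter": e.parameter, "covariate": e.covariate,
                 "form": e.form, "theta": e.theta}
                for e in self.covariate_effects
            ],
            "random_effects": {
                "iiv_sd": dict(self.random_effects.iiv_sd),
                "ruv_prop_sd": dict(self.random_effects.ruv_prop_sd),
                "ruv_add_sd": dict(self.random_effects.ruv_add_sd),
            },
            "covariate_defaults": dict(self.covariate_defaults),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelSpec":
        re_ = d.get("random_effects", {})
        return cls(
            name=d["name"],
            structure=d["structure"],
            typical_values=dict(d["typical_values"]),
            fixed_parameters=frozenset(d.get("fixed_parameters", ())),
            covariate_effects=tuple(
                CovariateEffect(**e) for e in d.get("covariate_effects", ())
            ),
            random_effects=RandomEffectsSpec(
                iiv_sd=dict(re_.get("iiv_sd", {})),
                ruv_prop_sd=dict(re_.get("ruv_prop_sd", {})),
                ruv_add_sd=dict(re_.get("ruv_add_sd", {})),
            ),
            covariate_defaults=dict(d.get("covariate_defaults", {})),
        )

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "ModelSpec":
        """Load from a path, an open stream, or a YAML document string."""
        import os

        if hasattr(source, "read"):
            return cls.from_dict(yaml.safe_load(source.read()))
        text = str(source)
        if "\n" not in text and os.path.exists(text):
            with open(text) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        return cls.from_dict(yaml.safe_load(text))

    def with_typical_values(self, **updates: float) -> "ModelSpec":
        tv = dict(self.typical_values)
        tv.update(updates)
        return replace(self, typical_values=tv)


@lru_cache(maxsize=None)
def builtin_model(name: str) -> ModelSpec:
    """Return one of the shipped parameterizations: ``M1``, ``M2`` or ``FINAL``."""
    key = name.upper()
    if key not in BUILTIN_MODELS:
        raise UnknownModelError(
            f"unknown model {name!r}; available: {', '.join(BUILTIN_MODELS)}")
    ref = resources.files("fluoxpk").joinpath(f"model_library/{key.lower()}.yaml")
    with ref.open() as fh:
        return ModelSpec.from_dict(yaml.safe_load(fh))


def _eta_mapping(eta) -> Mapping[str, float]:
    if eta is None:
        return {}
    values = getattr(eta, "values", eta)
    if callable(values):  # a plain dict's .values method, not an EtaVector field
        return eta
    return values


def individual_parameters(spec: ModelSpec, covariates: Mapping[str, float],
                          eta=None) -> PKParameters:
    """Individual parameters P_i = TV * covariate factors * exp(eta).

    ``eta`` may be a mapping or an :class:`~fluoxpk.estimation.EtaVector`;
    keys must be a subset of the model's IIV keys.  Covariates required by
    the model but absent from ``covariates`` fall back to the model's
    documented substitution defaults; if none exists the error names the
    covariate and model.
    """
    eta_map = _eta_mapping(eta)
    unknown = set(eta_map) - set(spec.iiv_keys)
    if unknown:
        raise ValueError(f"eta keys {sorted(unknown)} are not IIV keys of model {spec.name}")

    import math

    values = dict(spec.typical_values)
    for eff in spec.covariate_effects:
        if eff.covariate in covariates:
            cov_value = covariates[eff.covariate]
        elif eff.covariate in spec.covariate_defaults:
            cov_value = spec.covariate_defaults[eff.covariate]
        else:
            raise MissingCovariateError(
                f"model {spec.name!r} requires covariate {eff.covariate!r}")
        values[eff.parameter] = values[eff.parameter] * eff.factor(cov_value)
    for key, e in eta_map.items():
        values[key] = values[key] * math.exp(e)

    fields = {"cl_parent", "v_parent", "ka", "cl_metab", "v_metab", "fm", "mpr"}
    return PKParameters(**{k: v for k, v in values.items() if k in fields})


def milk_concentration(plasma: float, spec: ModelSpec) -> float:
    """Breast-milk concentration via the model's scalar milk-to-plasma ratio."""
    mpr = spec.typical_values.get("mpr")
    if mpr is None:
        raise UnsupportedStructureError(
            f"model {spec.name!r} carries no milk-to-plasma ratio")
    return plasma * mpr
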