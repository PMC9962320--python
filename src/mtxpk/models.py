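"""Catalog of published methotrexate population-PK models for pediatric ALL.

Six nonlinear mixed-effects models of high-dose methotrexate (HD-MTX)
disposition in children with acute lymphoid leukemia are carried as
declarative :class:`ModelSpec` records: structural model (2- or
3-compartment), covariate formulas for the typical parameter values,
log-normal inter-individual (IIV, eta) and inter-occasion (IOV, kappa)
variability expressed as coefficients of variation, and a residual
unexplained variability (RUV) model with proportional and/or additive
components.

Conventions
-----------
* Clearances in L/h, volumes in L, micro rate constants in 1/h,
  concentrations in umol/L.
* IIV/IOV coefficients of variation are interpreted as the standard
  deviation of the log-normal random effect, ``omega = CV / 100``
  (CVs above 100% in the sources make this approximate convention the
  only self-consistent reading); the ``log(1 + CV^2)`` convention is
  available via ``convention="lognormal"`` on :func:`omega_matrix`.
* Individual parameters are ``typical * exp(eta [+ kappa])``.
* Serum creatinine is carried in both mg/dL and umol/L
  (1 mg/dL = 88.42 umol/L) because one model's creatinine covariate is
  only dimensionally sensible in umol/L.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .expressions import evaluate, variables

__all__ = [
    "SCR_MGDL_TO_UMOL",
    "CovariateError",
    "MissingCovariateError",
    "CovariateRecord",
    "ModelSpec",
    "StructuralParams",
    "compute_egfr",
    "compute_bsa",
    "build_model_catalog",
    "get_model",
    "typical_params",
    "individual_params",
    "omega_matrix",
    "iov_variances",
    "residual_variance",
    "catalog_to_yaml",
    "catalog_from_yaml",
]

#: unit conversion for serum creatinine, mg/dL -> umol/L
SCR_MGDL_TO_UMOL = 88.42


class CovariateError(ValueError):
    """A covariate value violates its domain (non-positive, inconsistent units, ...)."""


class MissingCovariateError(KeyError):
    """A model requires a covariate that is neither recorded nor defaulted."""

    def __init__(self, model_name: str, covariate: str):
        super().__init__(covariate)
        self.model_name = model_name
        self.covariate = covariate

    def __str__(self) -> str:  # pragma: no cover - formatting
        return (
            f"model {self.model_name!r} requires covariate {self.covariate!r} "
            "which is missing and has no configured default"
        )


def compute_egfr(height: float, scr_mgdl: float) -> float:
    """Estimated glomerular filtration rate by the Bedside Schwartz formula.

    Parameters
    ----------
    height : float
        Body height in cm.
    scr_mgdl : float
        Serum creatinine in mg/dL.

    Returns
    -------
    float
        eGFR in mL/min/1.73 m^2, ``0.413 * height / scr_mgdl``.
    """
    if height <= 0 or scr_mgdl <= 0:
        raise CovariateError(
            f"height and serum creatinine must be positive (got height={height}, "
            f"scr={scr_mgdl})"
        )
    return 0.413 * height / scr_mgdl


def compute_bsa(height: float, weight: float, formula: str = "mosteller") -> float:
    """Body surface area (m^2) from height (cm) and weight (kg).

    ``formula`` is ``"mosteller"`` (default) or ``"dubois"``.
    """
    if height <= 0 or weight <= 0:
        raise CovariateError(
            f"height and weight must be positive (got height={height}, weight={weight})"
        )
    if formula == "mosteller":
        return math.sqrt(height * weight / 3600.0)
    if formula == "dubois":
        return 0.007184 * height**0.725 * weight**0.425
    raise ValueError(f"unknown BSA formula {formula!r}; choose 'mosteller' or 'dubois'")


@dataclass
class CovariateRecord:
    """One patient's covariates.

    Missing values are ``None``.  On construction, derivable fields are
    filled in: serum creatinine unit twins (mg/dL <-> umol/L), BSA from
    height/weight (Mosteller) and eGFR from height/creatinine (Bedside
    Schwartz) when absent.
    """

    patient_id: str
    sex: str | None = None  # "M" or "F"
    age: float | None = None  # years
    weight: float | None = None  # kg
    height: float | None = None  # cm
    bsa: float | None = None  # m^2
    scr_mgdl: float | None = None
    scr_umol: float | None = None
    egfr: float | None = None  # mL/min/1.73 m^2
    oh: float | None = None  # pre-chemotherapy alkalinization volume, mL
    risk_group: str | None = None  # LR / IR / HR
    bsa_formula: str = "mosteller"

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("M", "F"):
            raise CovariateError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("age", "weight", "height", "bsa", "scr_mgdl", "scr_umol", "egfr", "oh"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise CovariateError(f"covariate {name} must be strictly positive, got {val}")
        # creatinine unit consistency / derivation
        if self.scr_mgdl is not None and self.scr_umol is not None:
            expected = self.scr_mgdl * SCR_MGDL_TO_UMOL
            if not math.isclose(self.scr_umol, expected, rel_tol=1e-9):
                raise CovariateError(
                    f"inconsistent creatinine units: {self.scr_umol} umol/L vs "
                    f"{self.scr_mgdl} mg/dL * {SCR_MGDL_TO_UMOL}"
                )
        elif self.scr_mgdl is not None:
            self.scr_umol = self.scr_mgdl * SCR_MGDL_TO_UMOL
        elif self.scr_umol is not None:
            self.scr_mgdl = self.scr_umol / SCR_MGDL_TO_UMOL
        if self.bsa is None and self.height is not None and self.weight is not None:
            self.bsa = compute_bsa(self.height, self.weight, self.bsa_formula)
        if self.egfr is None and self.height is not None and self.scr_mgdl is not None:
            self.egfr = compute_egfr(self.height, self.scr_mgdl)


@dataclass
class ModelSpec:
    """Declarative description of one published population-PK model.

    ``params`` maps structural-parameter names to covariate formulas (safe
    arithmetic expressions over covariate names, see
    :mod:`mtxpk.expressions`).  ``iiv``/``iov`` carry per-parameter CVs in
    percent; the order of ``iiv`` keys fixes the eta-vector layout.
    """

    name: str
    n_compartments: int
    parameterization: str  # "clearance-volume" | "micro-constant"
    params: dict[str, str]
    iiv: dict[str, float] = field(default_factory=dict)
    iov: dict[str, float] = field(default_factory=dict)
    ruv_proportional: float = 0.0
    ruv_additive: float = 0.0  # umol/L
    required_covariates: list[str] = field(default_factory=list)
    covariate_defaults: dict[str, float] = field(default_factory=dict)
    gender_coding: str = "female=1"
    reference: str = ""

    def __post_init__(self) -> None:
        if self.n_compartments not in (2, 3):
            raise ValueError("n_compartments must be 2 or 3")
        if self.parameterization not in ("clearance-volume", "micro-constant"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        for p in list(self.iiv) + list(self.iov):
            if p not in self.params:
                raise ValueError(
                    f"model {self.name}: random effect on {p!r} but no formula produces it"
                )
        if self.ruv_proportional < 0 or self.ruv_additive < 0:
            raise ValueError("residual error components must be non-negative")
        if self.ruv_proportional == 0 and self.ruv_additive == 0:
            raise ValueError(
                f"model {self.name}: at least one residual error component must be positive"
            )

    @property
    def eta_order(self) -> list[str]:
        return list(self.iiv)

    @property
    def iov_order(self) -> list[str]:
        return list(self.iov)

    def covariate_names(self) -> set[str]:
        names: set[str] = set()
        for expr in self.params.values():
            names |= variables(expr)
        return names


@dataclass
class StructuralParams:
    """Realized structural parameters for one individual (one occasion)."""

    model_name: str
    values: dict[str, float]
    etas: np.ndarray
    kappas: np.ndarray | None = None
    n_compartments: int = 2
    parameterization: str = "clearance-volume"

    def __post_init__(self) -> None:
        for name, val in self.values.items():
            if not (np.isfinite(val) and val > 0):
                raise CovariateError(
                    f"model {self.model_name}: realized parameter {name} = {val} "
                    "is not strictly positive"
                )


def _gender_value(sex: str, coding: str) -> float:
    if coding == "female=1":
        return 1.0 if sex == "F" else 0.0
    if coding == "male=1":
        return 1.0 if sex == "M" else 0.0
    raise ValueError(f"unknown gender coding {coding!r}")


_COV_ATTR = {
    "age": "age",
    "weight": "weight",
    "height": "height",
    "bsa": "bsa",
    "scr_mgdl": "scr_mgdl",
    "scr_umol": "scr_umol",
    "egfr": "egfr",
    "oh": "oh",
}


def _environment(model: ModelSpec, cov: CovariateRecord) -> dict[str, float]:
    env: dict[str, float] = {}
    for name in model.covariate_names():
        if name == "gender":
            if cov.sex is not None:
                env["gender"] = _gender_value(cov.sex, model.gender_coding)
            elif "gender" in model.covariate_defaults:
                env["gender"] = float(model.covariate_defaults["gender"])
            else:
                raise MissingCovariateError(model.name, "gender")
            continue
        attr = _COV_ATTR.get(name)
        val = getattr(cov, attr) if attr else None
        if val is None:
            if name in model.covariate_defaults:
                val = float(model.covariate_defaults[name])
            else:
                raise MissingCovariateError(model.name, name)
        env[name] = float(val)
    return env


def typical_params(model: ModelSpec, cov: CovariateRecord) -> StructuralParams:
    """Typical (population) parameter values: covariate formulas at eta = kappa = 0."""
    env = _environment(model, cov)
    values = {p: evaluate(expr, env) for p, expr in model.params.items()}
    return StructuralParams(
        model_name=model.name,
        values=values,
        etas=np.zeros(len(model.eta_order)),
        kappas=None,
        n_compartments=model.n_compartments,
        parameterization=model.parameterization,
    )


def individual_params(
    model: ModelSpec,
    cov: CovariateRecord,
    etas: Sequence[float],
    kappas: np.ndarray | None = None,
    occasion: int = 0,
) -> StructuralParams:
    """Individual parameters: typical values scaled by ``exp(eta [+ kappa])``.

    ``kappas`` is an ``(n_occasions, n_iov_params)`` array of inter-occasion
    deviations; only the row for ``occasion`` is applied.  Parameters without
    a listed random effect stay at their typical values.
    """
    etas = np.asarray(etas, dtype=float)
    if etas.shape != (len(model.eta_order),):
        raise ValueError(
            f"model {model.name}: expected {len(model.eta_order)} etas, got shape {etas.shape}"
        )
    kap_row = np.zeros(len(model.iov_order))
    if kappas is not None:
        kappas = np.asarray(kappas, dtype=float)
        if kappas.ndim != 2 or kappas.shape[1] != len(model.iov_order):
            raise ValueError(
                f"model {model.name}: kappas must have shape (n_occasions, "
                f"{len(model.iov_order)}), got {kappas.shape}"
            )
        if not 0 <= occasion < kappas.shape[0]:
            raise ValueError(f"occasion {occasion} outside kappa array of {kappas.shape[0]}")
        kap_row = kappas[occasion]
    tp = typical_params(model, cov)
    values = dict(tp.values)
    for i, p in enumerate(model.eta_order):
        values[p] *= math.exp(etas[i])
    for j, p in enumerate(model.iov_order):
        values[p] *= math.exp(kap_row[j])
    return StructuralParams(
        model_name=model.name,
        values=values,
        etas=etas,
        kappas=kappas,
        n_compartments=model.n_compartments,
        parameterization=model.parameterization,
    )


def _cv_to_variance(cv_percent: float, convention: str) -> float:
    cv = cv_percent / 100.0
    if convention == "cv":
        return cv * cv
    if convention == "lognormal":
        return math.log1p(cv * cv)
    raise ValueError(f"unknown omega convention {convention!r}; choose 'cv' or 'lognormal'")


def omega_matrix(model: ModelSpec, convention: str = "cv") -> np.ndarray:
    """Diagonal covariance matrix of the inter-individual random effects eta.

    With the default ``"cv"`` convention the reported CV% is taken as the
    standard deviation of eta (``omega = CV/100``); ``"lognormal"`` uses
    ``omega^2 = log(1 + CV^2)``.
    """
    return np.diag([_cv_to_variance(model.iiv[p], convention) for p in model.eta_order])


def iov_variances(model: ModelSpec, convention: str = "cv") -> np.ndarray:
    """Per-parameter variances of the inter-occasion random effects kappa."""
    return np.array([_cv_to_variance(model.iov[p], convention) for p in model.iov_order])


def residual_variance(model: ModelSpec, ipred: float) -> float:
    """Residual (unexplained) error variance at an individual prediction.

    Combined error model: ``var = (prop * ipred)^2 + add^2`` in (umol/L)^2.
    """
    if ipred < 0:
        raise ValueError(f"individual prediction must be non-negative, got {ipred}")
    return (model.ruv_proportional * ipred) ** 2 + model.ruv_additive**2


def build_model_catalog(
    hui_renal: str = "absolute",
    zhang_gender_coding: str = "female=1",
) -> list[ModelSpec]:
    """The six published HD-MTX models for pediatric ALL.

    Parameters
    ----------
    hui_renal : str
        Parenthesization of the Hui renal-function term, whose printed form
        is ambiguous.  ``"absolute"`` (default) reads it as absolute GFR
        normalized to 192 mL/min: ``((egfr * bsa / 1.73) / 192)**0.256``.
        ``"literal"`` keeps the strict left-to-right reading
        ``(egfr * 1.73 / 192 * bsa)**0.256``.
    zhang_gender_coding : str
        Coding of the Zhang gender covariate (``"female=1"`` default: the
        negative coefficient lowers clearance for girls).
    """
    if hui_renal == "absolute":
        hui_cl = "7.73 * (bsa/0.735)**0.721 * ((egfr * bsa / 1.73) / 192)**0.256"
    elif hui_renal == "literal":
        hui_cl = "7.73 * (bsa/0.735)**0.721 * (egfr * 1.73 / 192 * bsa)**0.256"
    else:
        raise ValueError(f"unknown hui_renal option {hui_renal!r}")

    aumente = ModelSpec(
        name="aumente",
        n_compartments=2,
        parameterization="micro-constant",
        params={
            # age branch: exactly 10 years falls in the ">10 years" arm
            "CL": "where(age < 10, 0.287 * weight**0.876, 0.149 * weight)",
            "V1": "where(age < 10, 0.465 * weight, 0.437 * weight)",
            "K12": "0.0155",
            "K21": "0.0724",
        },
        iiv={"K12": 20.8, "K21": 35.2, "CL": 41.7, "V1": 41.6},
        ruv_proportional=0.162,
        ruv_additive=0.0035,
        required_covariates=["age", "weight"],
        covariate_defaults={"age": 5.0, "weight": 24.2},
        reference="Aumente et al., 2-compartment, Spanish ALL children",
    )
    gao = ModelSpec(
        name="gao",
        n_compartments=3,
        parameterization="clearance-volume",
        params={
            "CL": "6.9 * (weight/19)**0.75 * (1 + (scr_umol - 26) * (-0.0097))",
            "V1": "20.7 * (weight/19)",
            "V2": "41.0 * (weight/19)",
            "Q1": "0.255 * (weight/19)**0.75",
            "V3": "3.17 * (weight/19)",
            "Q2": "0.217 * (weight/19)**0.75",
        },
        iiv={"CL": 17.9, "V2": 26.2},
        ruv_proportional=0.354,  # exponential error ~ proportional
        ruv_additive=0.0,
        required_covariates=["weight", "scr_umol"],
        covariate_defaults={"weight": 19.0, "scr_umol": 0.3 * SCR_MGDL_TO_UMOL},
        reference="Gao et al., 3-compartment, largest development cohort (311 children)",
    )
    hui = ModelSpec(
        name="hui",
        n_compartments=2,
        parameterization="clearance-volume",
        params={
            "CL": hui_cl,
            "V1": "19.0 * (bsa/0.735)**0.985",
            "Q": "0.283 * (age/5.29)**0.278",
            "V2": "6.63",
        },
        iiv={"CL": 14.3, "V2": 34.6},
        iov={"CL": 14.9},
        ruv_proportional=0.302,
        ruv_additive=0.0,
        required_covariates=["bsa", "egfr", "age"],
        covariate_defaults={"bsa": 0.74, "age": 5.3},
        reference="Hui et al., 2-compartment with renal-function covariate and IOV on CL",
    )
    medellin = ModelSpec(
        name="medellin",
        n_compartments=2,
        parameterization="clearance-volume",
        params={
            "CL": "6.5 * bsa**0.62",
            "V1": "0.36 * weight",
            "Q": "0.41",
            "V2": "3.2",
        },
        iiv={"CL": 8.2, "V1": 25.9, "V2": 26.7},
        ruv_proportional=0.201,
        ruv_additive=0.0,
        required_covariates=["bsa", "weight"],
        covariate_defaults={"bsa": 0.79, "weight": 21.2},
        reference="Medellin-Garibay et al., 2-compartment, Mexican ALL children",
    )
    zhang = ModelSpec(
        name="zhang",
        n_compartments=2,
        parameterization="clearance-volume",
        params={
            # the alkalinization term sits additively outside the BSA product,
            # exactly as printed in the source
            "CL": "(5.04 * (1 - 0.278 * gender) * bsa**0.777 + (oh/100)**0.514)",
            "V1": "16.1",
            "Q": "0.203 * (age/10)**1.56",
            "V2": "7.05 * (age/10)**1.76",
        },
        iiv={"CL": 49.6, "V1": 29.4, "Q": 137.6, "V2": 107.7},
        ruv_proportional=0.190,
        ruv_additive=0.0872,
        required_covariates=["gender", "bsa", "oh", "age"],
        covariate_defaults={"bsa": 0.97, "age": 7.4, "gender": 0.0},
        gender_coding=zhang_gender_coding,
        reference="Zhang et al., 2-compartment with gender and alkalinization-volume covariates",
    )
    jonsson = ModelSpec(
        name="jonsson",
        n_compartments=2,
        parameterization="clearance-volume",
        params={
            "CL": "weight * 0.185",
            "V1": "weight * 1.27",
            "Q": "weight * 0.017",
            "V2": "weight * 1.02",
        },
        iiv={"CL": 109.0, "V1": 26.0, "Q": 22.0, "V2": 44.0},
        # residual error not reported in the source; 30% proportional assumed
        ruv_proportional=0.30,
        ruv_additive=0.0,
        required_covariates=["weight"],
        covariate_defaults={"weight": 19.0},
        reference="Jonsson et al., 2-compartment, weight-only covariate model",
    )
    return [aumente, gao, hui, medellin, zhang, jonsson]


def get_model(name: str, catalog: Iterable[ModelSpec] | None = None) -> ModelSpec:
    """Look up one model by name (case-insensitive) in a catalog."""
    catalog = list(catalog) if catalog is not None else build_model_catalog()
    for spec in catalog:
        if spec.name == name.lower():
            return spec
    available = ", ".join(s.name for s in catalog)
    raise KeyError(f"unknown model {name!r}; available: {available}")


def catalog_to_yaml(catalog: Iterable[ModelSpec], stream: IO[str] | None = None) -> str | None:
    """Serialize a catalog to YAML (one document per model)."""
    docs = [dataclasses.asdict(spec) for spec in catalog]
    return yaml.safe_dump_all(docs, stream, sort_keys=False)


def catalog_from_yaml(source: str | IO[str]) -> list[ModelSpec]:
    """Load a catalog from YAML text or an open stream."""
    return [ModelSpec(**doc) for doc in yaml.safe_load_all(source) if doc]
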