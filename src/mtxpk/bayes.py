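"""MAP-Bayesian (empirical Bayes) forecasting of individual concentrations.

Replicates the posthoc step of nonlinear mixed-effects software: with the
population model fixed, an individual's random effects ``eta`` (and
per-occasion ``kappa``) are estimated at the posterior mode given that
individual's observed concentrations,

    obj(eta, kappa) = sum_i [ log(2 pi s_i^2) + (y_i - f_i)^2 / s_i^2 ]
                      + eta' Omega^-1 eta + sum_occ kappa' Omega_IOV^-1 kappa,

with ``f_i`` the model-predicted concentration at observation time ``t_i``
and ``s_i^2`` the residual-error variance evaluated at ``f_i``.  Population
predictions (PRED) set all random effects to zero; individual predictions
(IPRED) use the MAP estimates.

Below-quantification-limit observations are excluded from the objective
and from all downstream metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
import yaml
from scipy.optimize import minimize

from .models import (
    CovariateRecord,
    ModelSpec,
    individual_params,
    iov_variances,
    omega_matrix,
    residual_variance,
)
from .pk import Regimen, concentration_profile

__all__ = [
    "Observation",
    "IndividualData",
    "EtaEstimate",
    "OptimizerConfig",
    "PredictionSeries",
    "EstimationError",
    "map_objective",
    "estimate_etas",
    "predict",
]


@dataclass(frozen=True)
class Observation:
    time: float  # h
    conc: float  # umol/L
    below_loq: bool = False


@dataclass
class IndividualData:
    """One patient: covariates, dosing regimen and concentration observations."""

    covariates: CovariateRecord
    regimen: Regimen
    observations: list[Observation]

    def __post_init__(self) -> None:
        if self.regimen.events:
            first_dose = self.regimen.events[0].start
            for obs in self.observations:
                if obs.time < first_dose:
                    raise ValueError(
                        f"patient {self.covariates.patient_id}: observation at "
                        f"{obs.time} h precedes the first dose at {first_dose} h"
                    )
        for obs in self.observations:
            if not obs.below_loq and obs.conc <= 0:
                raise ValueError(
                    f"patient {self.covariates.patient_id}: non-BLQ observation "
                    f"must have positive concentration, got {obs.conc}"
                )

    def usable_observations(self) -> list[Observation]:
        return [o for o in self.observations if not o.below_loq]


@dataclass
class EtaEstimate:
    etas: np.ndarray
    kappas: np.ndarray | None  # (n_occasions, n_iov), zeros where unobserved
    objective_value: float
    converged: bool
    n_starts_used: int


@dataclass
class OptimizerConfig:
    """Multi-start quasi-Newton settings for the MAP step (all seeded)."""

    n_starts: int = 5
    jitter_sd: float = 0.5
    gtol: float = 1e-8
    maxiter: int = 500
    seed: int = 0
    omega_convention: str = "cv"

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "OptimizerConfig":
        data = yaml.safe_load(source) or {}
        return cls(**data)


class EstimationError(RuntimeError):
    """All optimizer starts failed; carries per-start diagnostics."""

    def __init__(self, patient_id: str, model_name: str, diagnostics: list[str]):
        self.patient_id = patient_id
        self.model_name = model_name
        self.diagnostics = diagnostics
        super().__init__(
            f"MAP estimation failed for patient {patient_id!r} under model "
            f"{model_name!r}: " + "; ".join(diagnostics)
        )


@dataclass
class PredictionSeries:
    """Paired observation/prediction records at the retained sampling times."""

    patient_id: str
    model_name: str
    times: np.ndarray
    c_obs: np.ndarray
    c_pred: np.ndarray  # population prediction, eta = 0
    c_ipred: np.ndarray  # individual prediction, eta at MAP

    def __len__(self) -> int:
        return len(self.times)


def _occasions_with_obs(model: ModelSpec, data: IndividualData) -> list[int]:
    if not model.iov_order:
        return []
    occs = sorted({data.regimen.occasion_of(o.time) for o in data.usable_observations()})
    return occs


def _build_occasion_params(model, cov, etas, kappa_full):
    n_occ = kappa_full.shape[0]
    return [
        individual_params(model, cov, etas, kappas=kappa_full, occasion=i)
        for i in range(n_occ)
    ]


def _predict_at(model, data: IndividualData, etas, kappa_full, times):
    if model.iov_order:
        params = _build_occasion_params(model, data.covariates, etas, kappa_full)
    else:
        params = individual_params(model, data.covariates, etas)
    return concentration_profile(params, data.regimen, times).central_conc


class _MapProblem:
    """Packs (eta, kappa) into one optimization vector and evaluates the objective."""

    #: large finite penalty used inside the optimizer where an infinite
    #: objective would break finite-difference gradients; reported as +inf
    #: by the public objective
    PENALTY = 1e100

    def __init__(self, model: ModelSpec, data: IndividualData, config: OptimizerConfig):
        self.model = model
        self.data = data
        self.obs = data.usable_observations()
        self.times = np.array([o.time for o in self.obs])
        self.y = np.array([o.conc for o in self.obs])
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.y = self.y[order]
        self.n_eta = len(model.eta_order)
        self.omega_inv = None
        if self.n_eta:
            self.omega_inv = np.linalg.inv(omega_matrix(model, config.omega_convention))
        self.active_occasions = _occasions_with_obs(model, data)
        self.n_iov = len(model.iov_order)
        self.iov_var = iov_variances(model, config.omega_convention) if self.n_iov else None
        self.n_occ = data.regimen.n_occasions

    @property
    def dim(self) -> int:
        return self.n_eta + self.n_iov * len(self.active_occasions)

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        etas = np.asarray(x[: self.n_eta], dtype=float)
        kappa_full = np.zeros((self.n_occ, self.n_iov))
        for j, occ in enumerate(self.active_occasions):
            lo = self.n_eta + j * self.n_iov
            kappa_full[occ] = x[lo: lo + self.n_iov]
        return etas, kappa_full

    def prior(self, etas: np.ndarray, kappa_full: np.ndarray) -> float:
        val = 0.0
        if self.n_eta:
            val += float(etas @ self.omega_inv @ etas)
        if self.n_iov:
            for occ in self.active_occasions:
                val += float(np.sum(kappa_full[occ] ** 2 / self.iov_var))
        return val

    def __call__(self, x: np.ndarray) -> float:
        etas, kappa_full = self.unpack(x)
        val = self.prior(etas, kappa_full)
        if not len(self.times):
            return val
        try:
            f = _predict_at(self.model, self.data, etas, kappa_full, self.times)
        except (ValueError, ArithmeticError):
            return self.PENALTY
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            return self.PENALTY
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            for yi, fi in zip(self.y, f):
                s2 = residual_variance(self.model, fi)
                if s2 <= 0:
                    return self.PENALTY
                val += np.log(2.0 * np.pi * s2) + (yi - fi) ** 2 / s2
        if not np.isfinite(val):
            return self.PENALTY
        return val


def map_objective(
    etas: Sequence[float],
    kappas: np.ndarray | None,
    model: ModelSpec,
    data: IndividualData,
    config: OptimizerConfig | None = None,
) -> float:
    """MAP objective (−2 log posterior up to a constant) at a trial point.

    ``kappas`` is an ``(n_occasions, n_iov)`` array or ``None``; only
    occasions that carry usable observations contribute a prior term.
    Non-finite model predictions yield ``+inf``.
    """
    config = config or OptimizerConfig()
    problem = _MapProblem(model, data, config)
    x = np.zeros(problem.dim)
    x[: problem.n_eta] = np.asarray(etas, dtype=float)
    if kappas is not None:
        kappas = np.asarray(kappas, dtype=float)
        for j, occ in enumerate(problem.active_occasions):
            lo = problem.n_eta + j * problem.n_iov
            x[lo: lo + problem.n_iov] = kappas[occ]
    val = problem(x)
    return np.inf if val >= _MapProblem.PENALTY else val


def estimate_etas(
    model: ModelSpec,
    data: IndividualData,
    config: OptimizerConfig | None = None,
    rng: np.random.Generator | None = None,
) -> EtaEstimate:
    """MAP estimate of an individual's random effects.

    Quasi-Newton (BFGS) minimization from the prior mode (all zeros) plus
    ``n_starts - 1`` jittered restarts; the jitter stream is seeded from the
    configuration (or an explicitly supplied generator) so runs are
    reproducible.  With no usable observations the prior mode is returned
    directly.
    """
    config = config or OptimizerConfig()
    problem = _MapProblem(model, data, config)
    n_occ = data.regimen.n_occasions
    if not len(problem.times) or problem.dim == 0:
        kappa = np.zeros((n_occ, problem.n_iov)) if problem.n_iov else None
        return EtaEstimate(
            etas=np.zeros(problem.n_eta),
            kappas=kappa,
            objective_value=0.0,
            converged=True,
            n_starts_used=0,
        )

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    starts = [np.zeros(problem.dim)]
    for _ in range(max(0, config.n_starts - 1)):
        starts.append(rng.normal(0.0, config.jitter_sd, size=problem.dim))

    best = None
    diagnostics: list[str] = []
    n_used = 0
    for x0 in starts:
        if problem(x0) >= _MapProblem.PENALTY:
            diagnostics.append("non-finite objective at start")
            continue
        n_used += 1
        res = minimize(
            problem,
            x0,
            method="BFGS",
            options={"gtol": config.gtol, "maxiter": config.maxiter},
        )
        if not np.isfinite(res.fun) or res.fun >= _MapProblem.PENALTY:
            diagnostics.append(f"non-finite optimum: {res.message}")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise EstimationError(data.covariates.patient_id, model.name, diagnostics)

    # the optimizer must never end up worse than the prior mode it started from
    f0 = problem(np.zeros(problem.dim))
    if best.fun > f0:
        etas, kappa_full = problem.unpack(np.zeros(problem.dim))
        return EtaEstimate(etas, kappa_full if problem.n_iov else None, f0, True, n_used)

    etas, kappa_full = problem.unpack(best.x)
    grad_ok = bool(np.all(np.abs(getattr(best, "jac", np.zeros(1))) <= 1e-4))
    return EtaEstimate(
        etas=etas,
        kappas=kappa_full if problem.n_iov else None,
        objective_value=float(best.fun),
        converged=bool(best.success or grad_ok),
        n_starts_used=n_used,
    )


def predict(
    model: ModelSpec,
    data: IndividualData,
    estimate: EtaEstimate | None = None,
) -> PredictionSeries:
    """Population (PRED) and individual (IPRED) predictions at the retained times.

    PRED evaluates the model with all random effects at zero; IPRED uses the
    supplied MAP estimate (zeros if ``estimate`` is None).  Only non-BLQ
    observations are retained, in time order.
    """
    obs = sorted(data.usable_observations(), key=lambda o: o.time)
    times = np.array([o.time for o in obs])
    y = np.array([o.conc for o in obs])
    n_occ = data.regimen.n_occasions
    zero_kappa = np.zeros((n_occ, len(model.iov_order)))
    pred = _predict_at(model, data, np.zeros(len(model.eta_order)), zero_kappa, times)
    if estimate is None:
        ipred = pred.copy()
    else:
        kap = estimate.kappas if estimate.kappas is not None else zero_kappa
        ipred = _predict_at(model, data, estimate.etas, kap, times)
    return PredictionSeries(
        patient_id=data.covariates.patient_id,
        model_name=model.name,
        times=times,
        c_obs=y,
        c_pred=pred,
        c_ipred=ipred,
    )
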