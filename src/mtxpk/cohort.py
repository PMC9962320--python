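"""Virtual pediatric-ALL cohorts for exercising the evaluation pipeline.

Emulates the structure of a real HD-MTX therapeutic-drug-monitoring
dataset: correlated pediatric covariates (age-anchored height/weight, BSA,
serum creatinine, eGFR), risk-group-driven dosing (10% of the dose over
0.5 h plus 90% over 23.5 h per course), sampling at roughly 24/48/72/96 h
per course with nurse-timing jitter, residual assay noise, censoring below
the assay quantification limit (0.05 umol/L) and termination of sampling
once the concentration falls below the 0.1 umol/L follow-up threshold.
Ground-truth random effects are retained alongside each simulated patient
so that estimation-recovery tests can compare against them.

The age -> median weight/height anchor table below is a synthetic fixture
loosely following published pediatric growth medians; the multipliers are
calibrated so the generated cohort medians match the configured medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO

import numpy as np
import yaml

from .bayes import IndividualData, Observation
from .models import (
    CovariateRecord,
    ModelSpec,
    compute_bsa,
    compute_egfr,
    get_model,
    individual_params,
    iov_variances,
    omega_matrix,
    residual_variance,
)
from .pk import concat_regimens, concentration_profile, regimen_from_dose

__all__ = [
    "GROWTH_AGES",
    "GROWTH_WEIGHT",
    "GROWTH_HEIGHT",
    "CohortConfig",
    "SimulatedPatient",
    "sample_covariates",
    "simulate_tdm_course",
    "simulate_cohort",
    "make_validation_like_dataset",
]

# synthetic growth-anchor fixture: median weight (kg) and height (cm) by age (y)
GROWTH_AGES = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13], dtype=float)
GROWTH_WEIGHT = np.array(
    [10.0, 12.5, 14.5, 16.5, 18.5, 20.5, 23.0, 25.5, 28.5, 32.0, 36.0, 40.5, 45.5]
)
GROWTH_HEIGHT = np.array(
    [75.0, 87.0, 95.0, 102.0, 109.0, 115.0, 121.0, 127.0, 132.0, 137.0, 143.0, 149.0, 156.0]
)


@dataclass
class CohortConfig:
    """Study-design settings for one virtual cohort.

    Defaults mirror the validation cohort this generator emulates:
    51 patients, ages 1-13 y (median weight 19 kg, height 113 cm,
    BSA 0.77 m^2, creatinine 0.31 mg/dL), 40/51 male, HD-MTX doses of
    1-5 g/m^2 by risk group, sampling every ~24 h until the concentration
    drops below 0.1 umol/L, assay LLOQ 0.05 umol/L.
    """

    seed: int  # mandatory: every stream derives from it
    n_patients: int = 51
    age_range: tuple[float, float] = (1.0, 13.0)
    weight_median: float = 19.0
    weight_range: tuple[float, float] = (9.5, 62.0)
    weight_cv: float = 0.15  # multiplicative log-SD around the growth curve
    height_median: float = 113.0
    height_range: tuple[float, float] = (73.0, 168.0)
    height_cv: float = 0.04
    bsa_range: tuple[float, float] = (0.41, 1.60)
    scr_median: float = 0.31  # mg/dL
    scr_range: tuple[float, float] = (0.16, 0.71)
    scr_log_sd: float = 0.25
    male_fraction: float = 40.0 / 51.0
    oh_median: float = 200.0  # mL, alkalinization volume (generated covariate)
    oh_range: tuple[float, float] = (100.0, 400.0)
    oh_log_sd: float = 0.3
    risk_probs: dict[str, float] = field(
        default_factory=lambda: {"LR": 0.5, "IR": 0.35, "HR": 0.15}
    )
    dose_by_risk: dict[str, float] = field(
        default_factory=lambda: {"LR": 3.0, "IR": 5.0, "HR": 5.0}
    )
    courses_per_patient: int = 2
    course_interval_h: float = 336.0  # two weeks between courses
    sampling_times: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0)
    jitter_sd: float = 1.0  # h, truncated at +/- jitter_clip
    jitter_clip: float = 3.0
    lloq: float = 0.05  # umol/L
    stop_threshold: float = 0.1  # umol/L, sampling stops below this
    model_name: str = "medellin"
    sample_etas: bool = True
    residual_scale: float = 1.0  # 0 disables assay noise

    def __post_init__(self) -> None:
        for name in ("age_range", "weight_range", "height_range", "scr_range", "oh_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < min <= max, got ({lo}, {hi})")
        if not self.lloq < self.stop_threshold:
            raise ValueError("LLOQ must be below the follow-up stop threshold")

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "CohortConfig":
        data = yaml.safe_load(source) or {}
        for key in ("age_range", "weight_range", "height_range", "scr_range",
                    "oh_range", "sampling_times"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SimulatedPatient:
    """An IndividualData plus the ground-truth random effects that produced it."""

    data: IndividualData
    true_etas: np.ndarray
    true_kappas: np.ndarray | None
    model_name: str

    def strip(self) -> IndividualData:
        """The observable part only, as the dataset reader would produce it."""
        return self.data


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def _growth_anchor(config: CohortConfig) -> tuple[float, float]:
    """Multipliers putting the cohort medians at the configured medians.

    Age is log-uniform, so the cohort's median age is the geometric mean of
    the range; the growth curves are rescaled so that age maps to the
    configured median weight/height.
    """
    med_age = math.sqrt(config.age_range[0] * config.age_range[1])
    w_at = float(np.interp(med_age, GROWTH_AGES, GROWTH_WEIGHT))
    h_at = float(np.interp(med_age, GROWTH_AGES, GROWTH_HEIGHT))
    return config.weight_median / w_at, config.height_median / h_at


def _sample_one_covariates(config: CohortConfig, idx: int) -> CovariateRecord:
    rng = _patient_rng(config.seed, idx)
    w_factor, h_factor = _growth_anchor(config)
    lo, hi = config.age_range
    age = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    weight = float(np.interp(age, GROWTH_AGES, GROWTH_WEIGHT)) * w_factor
    weight *= math.exp(rng.normal(0.0, config.weight_cv))
    weight = float(np.clip(weight, *config.weight_range))
    height = float(np.interp(age, GROWTH_AGES, GROWTH_HEIGHT)) * h_factor
    height *= math.exp(rng.normal(0.0, config.height_cv))
    height = float(np.clip(height, *config.height_range))
    bsa = compute_bsa(height, weight)
    if not config.bsa_range[0] <= bsa <= config.bsa_range[1]:
        # clip BSA into range and restore the BSA-formula consistency by
        # recomputing weight from the clipped value
        bsa = float(np.clip(bsa, *config.bsa_range))
        weight = 3600.0 * bsa**2 / height
    scr = math.exp(rng.normal(math.log(config.scr_median), config.scr_log_sd))
    scr = float(np.clip(scr, *config.scr_range))
    sex = "M" if rng.uniform() < config.male_fraction else "F"
    oh = math.exp(rng.normal(math.log(config.oh_median), config.oh_log_sd))
    oh = float(np.clip(oh, *config.oh_range))
    risks = list(config.risk_probs)
    probs = np.array([config.risk_probs[r] for r in risks], dtype=float)
    risk = str(rng.choice(risks, p=probs / probs.sum()))
    return CovariateRecord(
        patient_id=f"SIM{idx + 1:03d}",
        sex=sex,
        age=age,
        weight=weight,
        height=height,
        bsa=bsa,
        scr_mgdl=scr,
        egfr=compute_egfr(height, scr),
        oh=oh,
        risk_group=risk,
    )


def sample_covariates(config: CohortConfig) -> list[CovariateRecord]:
    """Draw a cohort's covariates (deterministic given the seed)."""
    return [_sample_one_covariates(config, i) for i in range(config.n_patients)]


def _truncated_normal(rng: np.random.Generator, sd: float, clip: float) -> float:
    if sd == 0:
        return 0.0
    while True:
        val = rng.normal(0.0, sd)
        if abs(val) <= clip:
            return val


def simulate_tdm_course(
    cov: CovariateRecord,
    model: ModelSpec,
    config: CohortConfig,
    rng: np.random.Generator,
) -> SimulatedPatient:
    """Simulate one patient's TDM record under the generating model.

    Draws eta (and per-course kappa) from the model's variability, builds
    the multi-course regimen from the risk-group dose, simulates the true
    profile, samples at jittered nominal times, adds residual noise,
    censors below the LLOQ and stops each course's sampling after the first
    concentration below the follow-up threshold.
    """
    n_eta = len(model.eta_order)
    n_iov = len(model.iov_order)
    n_courses = config.courses_per_patient
    if config.sample_etas and n_eta:
        omega = omega_matrix(model)
        etas = rng.multivariate_normal(np.zeros(n_eta), omega)
    else:
        etas = np.zeros(n_eta)
    if config.sample_etas and n_iov:
        iov_sd = np.sqrt(iov_variances(model))
        kappas = rng.normal(0.0, iov_sd, size=(n_courses, n_iov))
    else:
        kappas = np.zeros((n_courses, n_iov)) if n_iov else None

    dose = config.dose_by_risk[cov.risk_group]
    regimen = concat_regimens(
        regimen_from_dose(dose, cov.bsa, course_start=i * config.course_interval_h)
        for i in range(n_courses)
    )

    # candidate sampling times (jittered), then simulate the truth once
    candidate_times: list[list[float]] = []
    for c in range(n_courses):
        start = c * config.course_interval_h
        course_times = []
        for t_nom in config.sampling_times:
            jitter = _truncated_normal(rng, config.jitter_sd, config.jitter_clip)
            course_times.append(start + t_nom + jitter)
        candidate_times.append(sorted(course_times))
    flat = sorted(t for ct in candidate_times for t in ct)
    if n_iov:
        params = [
            individual_params(model, cov, etas, kappas=kappas, occasion=i)
            for i in range(n_courses)
        ]
    else:
        params = individual_params(model, cov, etas)
    truth = dict(zip(flat, concentration_profile(params, regimen, flat).central_conc))

    observations: list[Observation] = []
    for course_times in candidate_times:
        for t in course_times:
            f = truth[t]
            noise = rng.normal() if config.residual_scale else 0.0
            y = f + math.sqrt(residual_variance(model, f)) * noise * config.residual_scale
            y = max(y, 0.0)
            observations.append(Observation(time=t, conc=y, below_loq=y < config.lloq))
            if y < config.stop_threshold:
                break  # follow-up for this course ends

    data = IndividualData(covariates=cov, regimen=regimen, observations=observations)
    return SimulatedPatient(
        data=data,
        true_etas=etas,
        true_kappas=kappas if n_iov else None,
        model_name=model.name,
    )


def simulate_cohort(config: CohortConfig, model: ModelSpec | None = None) -> list[SimulatedPatient]:
    """Simulate a full cohort (ground truth retained)."""
    model = model or get_model(config.model_name)
    patients = []
    for idx, cov in enumerate(sample_covariates(config)):
        # separate substream for the PK/noise draws so covariate sampling and
        # simulation do not interact
        rng = np.random.default_rng([config.seed, idx, 1])
        patients.append(simulate_tdm_course(cov, model, config, rng))
    return patients


def make_validation_like_dataset(config: CohortConfig, model: ModelSpec | None = None) -> list[IndividualData]:
    """A cohort with ground truth stripped, indistinguishable from read-in data."""
    return [p.strip() for p in simulate_cohort(config, model)]
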