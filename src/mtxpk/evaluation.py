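"""External-validation statistics for population-PK model predictions.

Given paired observed/predicted concentrations, computes relative
prediction errors

    PE_i = (C_i,pred - C_i,obs) / C_i,obs * 100   [%]

and summarizes them as median PE, mean PE (MPE) and relative root mean
squared error (RMSE = sqrt(mean(PE^2))).  A model is flagged as having
acceptable bias when both |median PE| and |MPE| are below 20%, and
acceptable precision when RMSE <= 30%.  Bland-Altman limits of agreement
(mean +/- 1.96 SD of PE) support the graphical bias assessment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bayes import (
    EstimationError,
    EtaEstimate,
    IndividualData,
    OptimizerConfig,
    PredictionSeries,
    estimate_etas,
    predict,
)
from .models import ModelSpec

__all__ = [
    "ErrorSummary",
    "BlandAltmanStats",
    "EvaluationReport",
    "prediction_errors",
    "summarize_errors",
    "acceptance_flags",
    "bland_altman",
    "evaluate_models",
]

logger = logging.getLogger(__name__)

BIAS_LIMIT = 20.0  # %, strict
PRECISION_LIMIT = 30.0  # %, inclusive


@dataclass
class ErrorSummary:
    model_name: str
    prediction_type: str  # "PRED" | "IPRED"
    n: int
    median_pe: float
    mpe: float
    rmse: float
    acceptable_bias: bool
    acceptable_precision: bool


@dataclass
class BlandAltmanStats:
    mean_pe: float
    lower_limit: float
    upper_limit: float
    x: np.ndarray  # reference value per point
    y: np.ndarray  # PE (%) per point


def _pick(series: PredictionSeries, which: str) -> np.ndarray:
    which = which.upper()
    if which == "PRED":
        return series.c_pred
    if which == "IPRED":
        return series.c_ipred
    raise ValueError(f"prediction type must be 'PRED' or 'IPRED', got {which!r}")


def prediction_errors(series: PredictionSeries, which: str = "IPRED") -> np.ndarray:
    """Relative prediction errors in percent for one patient's series."""
    if np.any(series.c_obs <= 0):
        raise ValueError(
            "zero/negative observed concentration reached the error computation; "
            "BLQ records must be excluded upstream"
        )
    pred = _pick(series, which)
    return (pred - series.c_obs) / series.c_obs * 100.0


def summarize_errors(pe: Sequence[float]) -> tuple[float, float, float, int]:
    """(median PE, MPE, RMSE, n) of a prediction-error vector (all in %)."""
    pe = np.asarray(pe, dtype=float)
    if pe.size == 0:
        raise ValueError("cannot summarize an empty prediction-error vector")
    median_pe = float(np.median(pe))
    mpe = float(np.mean(pe))
    rmse = float(np.sqrt(np.mean(pe**2)))
    # Jensen: sqrt(mean(PE^2)) >= |mean(PE)| always
    assert rmse >= abs(mpe) - 1e-9
    return median_pe, mpe, rmse, int(pe.size)


def acceptance_flags(median_pe: float, mpe: float, rmse: float) -> tuple[bool, bool]:
    """Bias flag: |median PE| and |MPE| strictly below 20%; precision: RMSE <= 30%."""
    bias = abs(median_pe) < BIAS_LIMIT and abs(mpe) < BIAS_LIMIT
    precision = rmse <= PRECISION_LIMIT
    return bias, precision


def _summary(model_name: str, which: str, pe: np.ndarray) -> ErrorSummary:
    median_pe, mpe, rmse, n = summarize_errors(pe)
    bias, precision = acceptance_flags(median_pe, mpe, rmse)
    return ErrorSummary(model_name, which, n, median_pe, mpe, rmse, bias, precision)


def bland_altman(
    series_list: PredictionSeries | Iterable[PredictionSeries],
    which: str = "PRED",
    x_axis: str = "mean",
) -> BlandAltmanStats:
    """Bland-Altman statistics of the prediction errors.

    ``x_axis`` picks the reference value per point: ``"mean"`` (default,
    the mean of observation and prediction) or ``"observed"``.  Limits of
    agreement are ``mean(PE) +/- 1.96 * SD(PE)`` with the sample SD.
    """
    if isinstance(series_list, PredictionSeries):
        series_list = [series_list]
    xs, ys = [], []
    for series in series_list:
        pred = _pick(series, which)
        pe = prediction_errors(series, which)
        if x_axis == "mean":
            xs.append((series.c_obs + pred) / 2.0)
        elif x_axis == "observed":
            xs.append(series.c_obs)
        else:
            raise ValueError(f"x_axis must be 'mean' or 'observed', got {x_axis!r}")
        ys.append(pe)
    x = np.concatenate(xs) if xs else np.zeros(0)
    y = np.concatenate(ys) if ys else np.zeros(0)
    if y.size < 2:
        raise ValueError("Bland-Altman statistics require at least two points")
    mean_pe = float(np.mean(y))
    sd = float(np.std(y, ddof=1))
    return BlandAltmanStats(
        mean_pe=mean_pe,
        lower_limit=mean_pe - 1.96 * sd,
        upper_limit=mean_pe + 1.96 * sd,
        x=x,
        y=y,
    )


@dataclass
class EvaluationReport:
    """Full external-evaluation output: summaries plus auditable detail."""

    summaries: list[ErrorSummary]
    series: dict[str, list[PredictionSeries]]  # model -> per-patient series
    estimates: dict[str, dict[str, EtaEstimate]]  # model -> patient -> estimate
    failures: dict[str, list[str]] = field(default_factory=dict)  # model -> patient ids

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": s.model_name,
                "prediction": s.prediction_type,
                "n": s.n,
                "median_pe_pct": s.median_pe,
                "mpe_pct": s.mpe,
                "rmse_pct": s.rmse,
                "acceptable_bias": s.acceptable_bias,
                "acceptable_precision": s.acceptable_precision,
            }
            for s in self.summaries
        ]
        return pd.DataFrame(rows)

    def gof_frame(self) -> pd.DataFrame:
        rows = []
        for model, series_list in self.series.items():
            for s in series_list:
                for t, obs, pred, ipred in zip(s.times, s.c_obs, s.c_pred, s.c_ipred):
                    rows.append(
                        {
                            "model": model,
                            "patient_id": s.patient_id,
                            "time_h": t,
                            "c_obs": obs,
                            "c_pred": pred,
                            "c_ipred": ipred,
                        }
                    )
        return pd.DataFrame(rows)

    def get_summary(self, model_name: str, which: str) -> ErrorSummary:
        for s in self.summaries:
            if s.model_name == model_name and s.prediction_type == which.upper():
                return s
        raise KeyError(f"no summary for {model_name}/{which}")


def evaluate_models(
    models: Iterable[ModelSpec],
    dataset: Sequence[IndividualData],
    config: OptimizerConfig | None = None,
) -> EvaluationReport:
    """Run the full external-evaluation pipeline.

    For every model and patient: population prediction (eta = 0), MAP
    estimation of the random effects, individual prediction, then pooled
    PE summaries per model and prediction type.  Patients whose MAP step
    fails are excluded from the IPRED summary (with a logged count) but
    retained in the PRED summary.  Results are deterministic given the
    dataset and optimizer seed: each patient uses a substream derived from
    the base seed and the patient's index.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset must contain at least one patient")
    config = config or OptimizerConfig()

    summaries: list[ErrorSummary] = []
    all_series: dict[str, list[PredictionSeries]] = {}
    all_estimates: dict[str, dict[str, EtaEstimate]] = {}
    failures: dict[str, list[str]] = {}
    for model in models:
        series_list: list[PredictionSeries] = []
        estimates: dict[str, EtaEstimate] = {}
        failed: list[str] = []
        pe_pred, pe_ipred = [], []
        for idx, patient in enumerate(dataset):
            rng = np.random.default_rng([config.seed, idx])
            estimate = None
            try:
                estimate = estimate_etas(model, patient, config, rng=rng)
            except EstimationError as exc:
                failed.append(patient.covariates.patient_id)
                logger.warning("%s", exc)
            series = predict(model, patient, estimate)
            if len(series) == 0:
                continue
            series_list.append(series)
            pe_pred.append(prediction_errors(series, "PRED"))
            if estimate is not None:
                estimates[patient.covariates.patient_id] = estimate
                pe_ipred.append(prediction_errors(series, "IPRED"))
        if failed:
            logger.warning(
                "model %s: %d/%d patients excluded from IPRED summaries",
                model.name, len(failed), len(dataset),
            )
        summaries.append(_summary(model.name, "PRED", np.concatenate(pe_pred)))
        summaries.append(_summary(model.name, "IPRED", np.concatenate(pe_ipred)))
        all_series[model.name] = series_list
        all_estimates[model.name] = estimates
        failures[model.name] = failed
    return EvaluationReport(
        summaries=summaries,
        series=all_series,
        estimates=all_estimates,
        failures=failures,
    )
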