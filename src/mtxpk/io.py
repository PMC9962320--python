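"""Flat-CSV dataset dialect: one event row per dose or observation.

Columns: ID, TIME (h), EVENT ('dose'|'obs'), AMT_MG, DUR_H, CONC (umol/L),
BLQ (0/1), then per-patient covariates repeated on every row (SEX, AGE, WT,
HT, BSA, SCR in mg/dL, EGFR, OH, RISK).  Dose rows carry AMT_MG/DUR_H and
no CONC; observation rows the reverse.  Amounts are converted mg <-> umol
at this boundary.  A deliberately simple dialect rather than the full
NONMEM EVID/MDV vocabulary: readable and loss-free for this design.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from .bayes import IndividualData, Observation
from .models import CovariateRecord
from .pk import InfusionEvent, Regimen, mg_to_umol, umol_to_mg

__all__ = ["COLUMNS", "DatasetError", "read_dataset", "write_dataset"]

COLUMNS = [
    "ID", "TIME", "EVENT", "AMT_MG", "DUR_H", "CONC", "BLQ",
    "SEX", "AGE", "WT", "HT", "BSA", "SCR", "EGFR", "OH", "RISK",
]

_COV_COLS = {
    "AGE": "age", "WT": "weight", "HT": "height", "BSA": "bsa",
    "SCR": "scr_mgdl", "EGFR": "egfr", "OH": "oh",
}


class DatasetError(ValueError):
    """A dataset file violates the dialect; message names the offending row."""


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return format(value, ".17g")
    return str(value)


def write_dataset(patients: Sequence[IndividualData], path: str | Path) -> None:
    """Write patients to the flat-CSV dialect (UTF-8, comma, header)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for patient in patients:
            cov = patient.covariates
            cov_cells = [
                cov.sex or "",
                _fmt(cov.age), _fmt(cov.weight), _fmt(cov.height), _fmt(cov.bsa),
                _fmt(cov.scr_mgdl), _fmt(cov.egfr), _fmt(cov.oh), cov.risk_group or "",
            ]
            rows = []
            for ev in patient.regimen.events:
                rows.append((ev.start, 0, [cov.patient_id, _fmt(ev.start), "dose",
                                           _fmt(umol_to_mg(ev.amount)), _fmt(ev.duration),
                                           "", ""] + cov_cells))
            for obs in patient.observations:
                rows.append((obs.time, 1, [cov.patient_id, _fmt(obs.time), "obs",
                                           "", "", _fmt(obs.conc),
                                           "1" if obs.below_loq else "0"] + cov_cells))
            for _, _, row in sorted(rows, key=lambda r: (r[0], r[1])):
                writer.writerow(row)


def _parse_float(cell: str, column: str, row_no: int) -> float | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError:
        raise DatasetError(f"row {row_no}: column {column} is not numeric: {cell!r}") from None


def read_dataset(path: str | Path) -> list[IndividualData]:
    """Read and validate a flat-CSV dataset.

    Validation errors (missing columns, unsorted times, negative values,
    observations before the first dose) name the offending row.  BLQ
    observations are flagged, not dropped.  Occasions: a dose event opens a
    new occasion unless it starts exactly at the previous dose event's end
    (the loading/maintenance pair of one course is a single occasion).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetError("empty file") from None
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise DatasetError(f"missing required columns: {', '.join(missing)}")
        idx = {c: header.index(c) for c in header}

        per_patient: dict[str, dict] = {}
        order: list[str] = []
        for row_no, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            pid = row[idx["ID"]].strip()
            if not pid:
                raise DatasetError(f"row {row_no}: empty patient ID")
            time = _parse_float(row[idx["TIME"]], "TIME", row_no)
            if time is None or time < 0:
                raise DatasetError(f"row {row_no}: TIME must be a non-negative number")
            event = row[idx["EVENT"]].strip().lower()
            if pid not in per_patient:
                sex = row[idx["SEX"]].strip() or None
                covs = {attr: _parse_float(row[idx[col]], col, row_no)
                        for col, attr in _COV_COLS.items()}
                for name, val in covs.items():
                    if val is not None and val <= 0:
                        raise DatasetError(f"row {row_no}: covariate {name} must be positive")
                per_patient[pid] = {
                    "cov": CovariateRecord(
                        patient_id=pid, sex=sex,
                        risk_group=row[idx["RISK"]].strip() or None,
                        **covs,
                    ),
                    "events": [], "obs": [], "last_time": -1.0,
                }
                order.append(pid)
            rec = per_patient[pid]
            if time < rec["last_time"]:
                raise DatasetError(f"row {row_no}: times for patient {pid} are not sorted")
            rec["last_time"] = time
            if event == "dose":
                amt = _parse_float(row[idx["AMT_MG"]], "AMT_MG", row_no)
                dur = _parse_float(row[idx["DUR_H"]], "DUR_H", row_no)
                if amt is None or dur is None:
                    raise DatasetError(f"row {row_no}: dose rows need AMT_MG and DUR_H")
                if amt < 0 or dur <= 0:
                    raise DatasetError(f"row {row_no}: negative amount or non-positive duration")
                if row[idx["CONC"]].strip():
                    raise DatasetError(f"row {row_no}: dose rows must not carry CONC")
                rec["events"].append(InfusionEvent(start=time, duration=dur,
                                                   amount=mg_to_umol(amt)))
            elif event == "obs":
                conc = _parse_float(row[idx["CONC"]], "CONC", row_no)
                if conc is None or conc < 0:
                    raise DatasetError(f"row {row_no}: observation rows need CONC >= 0")
                if row[idx["AMT_MG"]].strip() or row[idx["DUR_H"]].strip():
                    raise DatasetError(f"row {row_no}: observation rows must not carry AMT_MG/DUR_H")
                blq = row[idx["BLQ"]].strip() in ("1", "true", "True")
                if not rec["events"]:
                    raise DatasetError(
                        f"row {row_no}: observation for patient {pid} before any dose"
                    )
                rec["obs"].append(Observation(time=time, conc=conc, below_loq=blq))
            else:
                raise DatasetError(f"row {row_no}: EVENT must be 'dose' or 'obs', got {event!r}")

    patients = []
    for pid in order:
        rec = per_patient[pid]
        if not rec["events"]:
            raise DatasetError(f"patient {pid} has no dose events")
        occasions = []
        prev_end = None
        for ev in sorted(rec["events"], key=lambda e: e.start):
            if prev_end is None or ev.start > prev_end + 1e-9:
                occasions.append(ev.start)
            prev_end = ev.end
        regimen = Regimen(events=rec["events"], occasion_starts=occasions)
        patients.append(IndividualData(covariates=rec["cov"], regimen=regimen,
                                       observations=rec["obs"]))
    return patients
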