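"""Linear mammillary compartment kinetics under piecewise-constant infusions.

Amounts are carried in umol (methotrexate molar mass 454.44 g/mol) so that
central-compartment concentration is ``amount / V1`` in umol/L.  Profiles
are propagated exactly (to matrix-exponential accuracy) segment by segment:
within each segment the infusion rate vector is constant and the state
advances by

    A(t + dt) = E A(t) + (E - I) M^-1 b,      E = expm(M dt),

with ``M`` the first-order rate matrix and ``b`` the input rate into the
central compartment.  An independent adaptive-ODE reference integrator is
provided for verification.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .models import StructuralParams

__all__ = [
    "MTX_MOLAR_MASS",
    "mg_to_umol",
    "umol_to_mg",
    "InfusionEvent",
    "Regimen",
    "ConcentrationProfile",
    "rate_matrix",
    "concentration_profile",
    "ode_reference",
    "regimen_from_dose",
    "concat_regimens",
]

#: methotrexate molar mass, g/mol
MTX_MOLAR_MASS = 454.44


def mg_to_umol(mg: float) -> float:
    return mg / MTX_MOLAR_MASS * 1000.0


def umol_to_mg(umol: float) -> float:
    return umol * MTX_MOLAR_MASS / 1000.0


@dataclass(frozen=True)
class InfusionEvent:
    """One constant-rate intravenous infusion."""

    start: float  # h
    duration: float  # h
    amount: float  # umol

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"infusion duration must be positive, got {self.duration}")
        if self.amount < 0:
            raise ValueError(f"infusion amount must be non-negative, got {self.amount}")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def rate(self) -> float:
        return self.amount / self.duration  # umol/h


@dataclass
class Regimen:
    """A set of infusion events plus occasion (course) boundaries.

    ``occasion_starts`` partitions time into treatment occasions for models
    with inter-occasion variability; times before the first boundary belong
    to occasion 0.  Overlapping events are allowed (superposition).
    """

    events: list[InfusionEvent]
    occasion_starts: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.start)
        if not self.occasion_starts and self.events:
            self.occasion_starts = [self.events[0].start]
        self.occasion_starts = sorted(self.occasion_starts)

    @property
    def n_occasions(self) -> int:
        return max(1, len(self.occasion_starts))

    def occasion_of(self, t: float) -> int:
        if not self.occasion_starts:
            return 0
        return max(0, bisect.bisect_right(self.occasion_starts, t) - 1)


@dataclass
class ConcentrationProfile:
    times: np.ndarray  # h
    central_conc: np.ndarray  # umol/L
    amounts: np.ndarray | None = None  # (n_times, n_compartments), umol


def rate_matrix(params: StructuralParams) -> np.ndarray:
    """First-order rate matrix M (1/h) of the mammillary system dA/dt = M A + input.

    Clearance/volume parameterization uses ``k10 = CL/V1``, ``k1j = Qj/V1``,
    ``kj1 = Qj/Vj``; the micro-constant form takes K12/K21 directly (with
    ``k10 = CL/V1``).  Three-compartment models have both peripheral
    compartments exchanging with the central one only.
    """
    v = params.values
    if params.parameterization == "micro-constant":
        k10 = v["CL"] / v["V1"]
        k12, k21 = v["K12"], v["K21"]
        return np.array([[-(k10 + k12), k21], [k12, -k21]])
    if params.n_compartments == 2:
        k10 = v["CL"] / v["V1"]
        k12 = v["Q"] / v["V1"]
        k21 = v["Q"] / v["V2"]
        return np.array([[-(k10 + k12), k21], [k12, -k21]])
    k10 = v["CL"] / v["V1"]
    k12 = v["Q1"] / v["V1"]
    k21 = v["Q1"] / v["V2"]
    k13 = v["Q2"] / v["V1"]
    k31 = v["Q2"] / v["V3"]
    return np.array(
        [
            [-(k10 + k12 + k13), k21, k31],
            [k12, -k21, 0.0],
            [k13, 0.0, -k31],
        ]
    )


def _per_occasion(params, regimen: Regimen) -> list[StructuralParams]:
    if isinstance(params, StructuralParams):
        return [params] * regimen.n_occasions
    params = list(params)
    if len(params) != regimen.n_occasions:
        raise ValueError(
            f"expected {regimen.n_occasions} per-occasion parameter sets, got {len(params)}"
        )
    return params


def _breakpoints(regimen: Regimen, times: np.ndarray) -> np.ndarray:
    pts = [0.0]
    for ev in regimen.events:
        pts += [ev.start, ev.end]
    pts += list(regimen.occasion_starts)
    pts += list(times)
    return np.unique(np.asarray(pts, dtype=float))


def _segment_rate(regimen: Regimen, t0: float, t1: float) -> float:
    mid = 0.5 * (t0 + t1)
    return sum(ev.rate for ev in regimen.events if ev.start <= mid <= ev.end)


def concentration_profile(params, regimen: Regimen, times) -> ConcentrationProfile:
    """Central-compartment concentration at the query times.

    ``params`` is a single :class:`StructuralParams` or a sequence of
    per-occasion parameter sets (one per entry of
    ``regimen.occasion_starts``), for models whose clearance varies between
    treatment courses.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(times < 0) or np.any(np.diff(times) < 0)):
        raise ValueError("query times must be non-negative and sorted")
    occ_params = _per_occasion(params, regimen)
    n = occ_params[0].n_compartments

    grid = _breakpoints(regimen, times)
    A = np.zeros(n)
    amounts = {grid[0]: A.copy()}
    mats: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    # extreme random-effect trial points can overflow the matrix exponential;
    # the resulting non-finite amounts propagate to callers, which guard on them
    with np.errstate(over="ignore", invalid="ignore"):
        for t0, t1 in zip(grid[:-1], grid[1:]):
            dt = t1 - t0
            occ = regimen.occasion_of(t0)
            if occ not in mats:
                M = rate_matrix(occ_params[occ])
                mats[occ] = (M, np.linalg.inv(M))
            M, Minv = mats[occ]
            E = expm(M * dt)
            rate = _segment_rate(regimen, t0, t1)
            if rate > 0:
                b = np.zeros(n)
                b[0] = rate
                s = Minv @ b
                A = E @ (A + s) - s
            else:
                A = E @ A
            A = np.maximum(A, 0.0)  # clip tiny negative round-off
            amounts[t1] = A.copy()

    out_amounts = np.array([amounts[t] for t in times]) if times.size else np.zeros((0, n))
    v1 = np.array(
        [occ_params[regimen.occasion_of(t)].values["V1"] for t in times]
    ) if times.size else np.zeros(0)
    conc = out_amounts[:, 0] / v1 if times.size else np.zeros(0)
    return ConcentrationProfile(times=times, central_conc=conc, amounts=out_amounts)


def ode_reference(params, regimen: Regimen, times, rtol: float = 1e-10,
                  atol: float = 1e-12) -> ConcentrationProfile:
    """Independent adaptive-ODE solution of the same system (verification oracle).

    Integrates segment by segment with LSODA at tight tolerances so the
    discontinuous infusion rate is never smeared across a boundary.
    """
    times = np.asarray(times, dtype=float)
    occ_params = _per_occasion(params, regimen)
    n = occ_params[0].n_compartments
    grid = _breakpoints(regimen, times)
    A = np.zeros(n)
    amounts = {grid[0]: A.copy()}
    for t0, t1 in zip(grid[:-1], grid[1:]):
        occ = regimen.occasion_of(t0)
        M = rate_matrix(occ_params[occ])
        rate = _segment_rate(regimen, t0, t1)
        b = np.zeros(n)
        b[0] = rate

        def rhs(_t, y):
            return M @ y + b

        sol = solve_ivp(rhs, (t0, t1), A, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=[t1])
        A = sol.y[:, -1]
        amounts[t1] = A.copy()
    out_amounts = np.array([amounts[t] for t in times]) if times.size else np.zeros((0, n))
    v1 = np.array(
        [occ_params[regimen.occasion_of(t)].values["V1"] for t in times]
    ) if times.size else np.zeros(0)
    conc = out_amounts[:, 0] / v1 if times.size else np.zeros(0)
    return ConcentrationProfile(times=times, central_conc=conc, amounts=out_amounts)


def regimen_from_dose(total_dose: float, bsa: float, course_start: float = 0.0) -> Regimen:
    """HD-MTX course: 10% of the dose over 0.5 h, the remaining 90% over 23.5 h.

    ``total_dose`` is in g/m^2, ``bsa`` in m^2; amounts are converted to umol.
    Doses outside the 1-5 g/m^2 range seen in practice trigger a warning.
    """
    if total_dose <= 0 or bsa <= 0:
        raise ValueError(f"dose and BSA must be positive (got {total_dose} g/m^2, {bsa} m^2)")
    if not 1.0 <= total_dose <= 5.0:
        warnings.warn(
            f"dose {total_dose} g/m^2 outside the typical 1-5 g/m^2 HD-MTX range",
            stacklevel=2,
        )
    total_umol = mg_to_umol(total_dose * bsa * 1000.0)
    events = [
        InfusionEvent(start=course_start, duration=0.5, amount=0.1 * total_umol),
        InfusionEvent(start=course_start + 0.5, duration=23.5, amount=0.9 * total_umol),
    ]
    return Regimen(events=events, occasion_starts=[course_start])


def concat_regimens(regimens) -> Regimen:
    """Merge per-course regimens into one multi-occasion regimen."""
    events: list[InfusionEvent] = []
    occasions: list[float] = []
    for reg in regimens:
        events += reg.events
        occasions += reg.occasion_starts
    return Regimen(events=events, occasion_starts=sorted(set(occasions)))
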