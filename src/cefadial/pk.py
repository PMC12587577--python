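"""Event-driven linear pharmacokinetic engine with dialysis-gated clearance.

The model is a one-compartment (optionally two-compartment) linear system
driven by zero-order intravenous infusions. Total clearance is piecewise
constant in time: the subject's residual elimination clearance ``CL`` acts
always, and the dialysis-machine clearance ``CLdial`` is added only while a
hemodialysis session is running.  Between any two consecutive "breakpoints"
(infusion starts/ends, session starts/ends) both the input rate and the
elimination rate constant are constant, so the concentration obeys

    C(t0 + dt) = Cinf + (C(t0) - Cinf) * exp(-k * dt),
    Cinf = R / (k * V),   k = (CL + CLdial * 1{session}) / V,

which the engine propagates exactly segment by segment.  Units are hours,
mg, L and mg/L throughout; time 0 is the first event of a subject record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm


class ScheduleError(ValueError):
    """Invalid event schedule (overlapping sessions, out-of-range times...)."""


class ParameterError(ValueError):
    """Invalid structural parameters."""


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters.

    cl_residual
        Residual elimination clearance (non-renal + residual renal), L/h.
    v_central
        Central volume of distribution, L.
    cl_dialysis
        Dialysis-machine clearance, L/h; acts only during sessions.
    q_inter, v_peripheral
        Inter-compartmental clearance (L/h) and peripheral volume (L) for
        the optional two-compartment extension; both present or both absent.
    """

    cl_residual: float
    v_central: float
    cl_dialysis: float = 0.0
    q_inter: float | None = None
    v_peripheral: float | None = None

    def __post_init__(self) -> None:
        if not (self.cl_residual > 0):
            raise ParameterError(f"cl_residual must be > 0, got {self.cl_residual}")
        if not (self.v_central > 0):
            raise ParameterError(f"v_central must be > 0, got {self.v_central}")
        if self.cl_dialysis < 0:
            raise ParameterError(f"cl_dialysis must be >= 0, got {self.cl_dialysis}")
        if (self.q_inter is None) != (self.v_peripheral is None):
            raise ParameterError("q_inter and v_peripheral must be given together")
        if self.q_inter is not None and (self.q_inter < 0 or self.v_peripheral <= 0):
            raise ParameterError("invalid two-compartment parameters")

    @property
    def is_two_compartment(self) -> bool:
        return self.q_inter is not None


@dataclass(frozen=True)
class InfusionEvent:
    """Zero-order infusion: `amount` mg delivered over `duration` h from `start`."""

    start: float
    duration: float
    amount: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ScheduleError(f"infusion duration must be > 0, got {self.duration}")
        if self.amount <= 0:
            raise ScheduleError(f"infusion amount must be > 0, got {self.amount}")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def rate(self) -> float:
        return self.amount / self.duration


@dataclass(frozen=True)
class DialysisSession:
    """Hemodialysis session [start, end] h; optional per-session membrane area."""

    start: float
    end: float
    dmsa: float | None = None
    clearance_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ScheduleError(f"session end must exceed start ({self.start}, {self.end})")
        if self.clearance_scale < 0:
            raise ScheduleError("clearance_scale must be >= 0")


@dataclass
class EventSchedule:
    """A subject's infusions and dialysis sessions on one timeline [0, horizon]."""

    infusions: list[InfusionEvent] = field(default_factory=list)
    sessions: list[DialysisSession] = field(default_factory=list)
    horizon: float = 0.0

    def __post_init__(self) -> None:
        self.infusions = sorted(self.infusions, key=lambda e: e.start)
        self.sessions = sorted(self.sessions, key=lambda s: s.start)
        for ev in self.infusions:
            if ev.start < 0 or ev.end > self.horizon + 1e-9:
                raise ScheduleError(f"infusion [{ev.start}, {ev.end}] outside [0, {self.horizon}]")
        prev_end = -math.inf
        for s in self.sessions:
            if s.start < 0 or s.end > self.horizon + 1e-9:
                raise ScheduleError(f"session [{s.start}, {s.end}] outside [0, {self.horizon}]")
            if s.start < prev_end - 1e-9:
                raise ScheduleError("dialysis sessions overlap")
            prev_end = s.end


@dataclass(frozen=True)
class ConcentrationProfile:
    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.conc):
            raise ValueError("times and conc must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def breakpoints(schedule: EventSchedule) -> np.ndarray:
    """Union of {0, horizon, infusion starts/ends, session starts/ends}, sorted."""
    pts = [0.0, float(schedule.horizon)]
    for ev in schedule.infusions:
        pts += [ev.start, ev.end]
    for s in schedule.sessions:
        pts += [s.start, s.end]
    return np.unique(np.asarray(pts, dtype=float))


# ---------------------------------------------------------------------------
# Compiled simulation plan: the segment structure is independent of the
# parameters, so estimation code can reuse it across thousands of likelihood
# evaluations.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationPlan:
    """Pre-resolved piecewise-constant structure of a schedule.

    grid
        All breakpoints plus requested output times, sorted and unique.
    seg_dt, seg_rate, seg_dial
        Per segment j (between grid[j] and grid[j+1]): duration, total
        infusion rate (mg/h) and effective dialysis multiplier
        (clearance_scale * (session dmsa override applied upstream), 0
        outside sessions).
    out_idx
        Indices into `grid` of the requested output times.
    """

    grid: np.ndarray
    seg_dt: np.ndarray
    seg_rate: np.ndarray
    seg_dial: np.ndarray
    out_idx: np.ndarray


def compile_plan(schedule: EventSchedule, times: Sequence[float]) -> SimulationPlan:
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < -1e-9 or times.max() > schedule.horizon + 1e-9):
        raise ScheduleError("requested times outside [0, horizon]")
    grid = np.unique(np.concatenate([breakpoints(schedule), times]))
    mid = 0.5 * (grid[:-1] + grid[1:])
    seg_rate = np.zeros(mid.size)
    for ev in schedule.infusions:
        seg_rate[(mid > ev.start) & (mid < ev.end)] += ev.rate
    seg_dial = np.zeros(mid.size)
    for s in schedule.sessions:
        seg_dial[(mid > s.start) & (mid < s.end)] = s.clearance_scale
    out_idx = np.searchsorted(grid, times)
    return SimulationPlan(grid, np.diff(grid), seg_rate, seg_dial, out_idx)


def _propagate_py(seg_dt, seg_rate, k, v, c0):
    n = seg_dt.shape[0]
    out = np.empty(n + 1)
    out[0] = c = c0
    for j in range(n):
        x = k[j] * seg_dt[j]
        c = c * math.exp(-x) - seg_rate[j] / (k[j] * v) * math.expm1(-x)
        out[j + 1] = c
    return out


try:  # optional JIT of the hot loop
    from numba import njit

    _propagate = njit(cache=True)(_propagate_py)
    _propagate(np.ones(1), np.ones(1), np.ones(1), 1.0, 0.0)  # warm compile
except Exception:  # pragma: no cover - numba simply absent
    _propagate = _propagate_py


def conc_at(plan: SimulationPlan, params: StructuralParams, c0: float = 0.0) -> np.ndarray:
    """Concentration at the plan's output times (fast path for estimation)."""
    k = (params.cl_residual + params.cl_dialysis * plan.seg_dial) / params.v_central
    grid_conc = _propagate(plan.seg_dt, plan.seg_rate, k, params.v_central, c0)
    return grid_conc[plan.out_idx]


def grid_conc(plan: SimulationPlan, params: StructuralParams, c0: float = 0.0) -> np.ndarray:
    """Concentration at every grid point of the plan."""
    k = (params.cl_residual + params.cl_dialysis * plan.seg_dial) / params.v_central
    return _propagate(plan.seg_dt, plan.seg_rate, k, params.v_central, c0)


def simulate_profile(
    params: StructuralParams,
    schedule: EventSchedule,
    times: Sequence[float],
    c0: float = 0.0,
) -> ConcentrationProfile:
    """Exact total plasma concentration at `times` for a one-compartment subject.

    `c0` is the concentration at time 0 (useful for bolus-loaded scenarios).
    """
    times = np.unique(np.asarray(times, dtype=float))
    plan = compile_plan(schedule, times)
    return ConcentrationProfile(times, conc_at(plan, params, c0))


def simulate_profile_2cmt(
    params: StructuralParams,
    schedule: EventSchedule,
    times: Sequence[float],
    x0: tuple[float, float] = (0.0, 0.0),
) -> ConcentrationProfile:
    """Central-compartment concentration for the two-compartment extension.

    Per segment the amount vector A = (A1, A2) obeys dA/dt = M A + u with
    constant M, u; the exact step is A(dt) = A* + expm(M dt)(A0 - A*) with
    A* = -M^-1 u.  `x0` gives initial amounts (mg) in the two compartments.
    """
    if not params.is_two_compartment:
        raise ParameterError("two-compartment fields (q_inter, v_peripheral) required")
    times = np.unique(np.asarray(times, dtype=float))
    plan = compile_plan(schedule, times)
    v1, v2, q = params.v_central, params.v_peripheral, params.q_inter
    a = np.array(x0, dtype=float)
    out = np.empty(plan.grid.size)
    out[0] = a[0] / v1
    for j in range(plan.seg_dt.size):
        cl_tot = params.cl_residual + params.cl_dialysis * plan.seg_dial[j]
        # augmented system [a1, a2, 1]: exact step even when M is singular
        maug = np.array([[-(cl_tot + q) / v1, q / v2, plan.seg_rate[j]],
                         [q / v1, -q / v2, 0.0],
                         [0.0, 0.0, 0.0]])
        step = expm(maug * plan.seg_dt[j]) @ np.array([a[0], a[1], 1.0])
        a = step[:2]
        out[j + 1] = a[0] / v1
    return ConcentrationProfile(times, out[plan.out_idx])


def half_life(params: StructuralParams, phase: str = "interdialytic") -> float:
    """Elimination half-life (h) in the requested phase.

    ``interdialytic`` uses CL alone, ``intradialytic`` uses CL + CLdial.
    """
    if phase == "interdialytic":
        cl = params.cl_residual
    elif phase == "intradialytic":
        cl = params.cl_residual + params.cl_dialysis
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return math.log(2.0) * params.v_central / cl


@dataclass(frozen=True)
class ExposureMetrics:
    cmin: float
    cmax: float
    auc: float
    auc_dialysis: float
    time_in_band: float  # fraction of the window with lo <= C <= hi


def _crossing_time(c0: float, cinf: float, k: float, target: float) -> float:
    # time within a segment at which C(t) = target; caller guarantees bracketing
    return math.log((c0 - cinf) / (target - cinf)) / k


def exposure_metrics(
    params: StructuralParams,
    schedule: EventSchedule,
    window: tuple[float, float],
    band: tuple[float, float] = (0.0, math.inf),
    c0: float = 0.0,
) -> ExposureMetrics:
    """Exact exposure summaries over `window` = (t0, t1).

    On each inter-breakpoint segment C(t) relaxes monotonically toward its
    asymptote Cinf = R/(kV), so extrema occur at segment endpoints; the AUC
    and band-crossing times have closed forms per segment.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t1 > t0")
    lo, hi = band
    plan = compile_plan(schedule, [t0, t1])
    k_arr = (params.cl_residual + params.cl_dialysis * plan.seg_dial) / params.v_central
    conc = _propagate(plan.seg_dt, plan.seg_rate, k_arr, params.v_central, c0)

    cmin, cmax = math.inf, -math.inf
    auc = auc_dial = t_band = 0.0
    for j in range(plan.seg_dt.size):
        a, b = plan.grid[j], plan.grid[j + 1]
        s, e = max(a, t0), min(b, t1)
        if e <= s:
            continue
        k = k_arr[j]
        cinf = plan.seg_rate[j] / (k * params.v_central)
        # concentration at the clipped sub-segment endpoints
        cs = cinf + (conc[j] - cinf) * math.exp(-k * (s - a))
        ce = cinf + (conc[j] - cinf) * math.exp(-k * (e - a))
        cmin, cmax = min(cmin, cs, ce), max(cmax, cs, ce)
        dt = e - s
        seg_auc = cinf * dt + (cs - cinf) * -math.expm1(-k * dt) / k
        auc += seg_auc
        if plan.seg_dial[j] > 0:
            auc_dial += seg_auc
        # time with lo <= C <= hi on a monotone segment
        clo_, chi_ = (cs, ce) if cs <= ce else (ce, cs)
        if chi_ < lo or clo_ > hi:
            continue
        t_enter, t_exit = 0.0, dt
        for target, entering in ((lo, True), (hi, False)):
            if not math.isfinite(target) or target <= 0 and entering and lo <= 0:
                continue
            if min(cs, ce) < target < max(cs, ce):
                tc = _crossing_time(cs, cinf, k, target)
                rising = ce > cs
                if (target == lo and not rising) or (target == hi and rising):
                    t_exit = min(t_exit, tc)
                else:
                    t_enter = max(t_enter, tc)
        t_band += max(0.0, t_exit - t_enter)
    return ExposureMetrics(cmin, cmax, auc, auc_dial, t_band / (t1 - t0))
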