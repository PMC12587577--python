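"""Synthetic study-like datasets.

The study's raw concentration data are not publicly deposited, so this
module generates stand-ins that emulate its design: six children on
maintenance hemodialysis receiving 30-60 min cefazolin infusions every
6-48 h with about three 4-h dialysis sessions per week, sparsely sampled
at times plausible for routine therapeutic drug monitoring (troughs,
end-of-infusion peaks, pre-/intra-/post-dialysis draws).  Concentrations
are simulated under a population model with log-normal BSV and the chosen
residual-error model, and the generating "truth" (etas, individual
parameters, noise-free predictions) is returned for recovery tests.

A denser 100-subject "rich design" used for parameter-recovery experiments
is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .covariates import SubjectCovariates
from .dataset import ObservationDataset, SubjectData
from .model import PopulationModel, apply_residual_error
from .pk import DialysisSession, EventSchedule, InfusionEvent, compile_plan, conc_at


def table1_fixture() -> tuple[list[SubjectCovariates], list[int]]:
    """The six study patients' covariates and their dialysis-session counts.

    Heights are converted from the published cm to meters; patient 6 used
    two membranes (1.4 and 1.7 m^2) and is represented by their mean.
    """
    rows = [
        # bw kg, ht cm, sex, albumin g/L, dmsa m^2, sessions
        (23.2, 135, "male", 26.1, 1.0, 1),
        (24.5, 136, "male", 29.2, 1.0, 10),
        (47.5, 170, "male", 47.0, 1.5, 3),
        (11.4, 83, "male", 37.2, 0.2, 13),
        (12.3, 89, "male", 26.3, 0.3, 6),
        (51.0, 164, "female", 34.6, 1.55, 13),
    ]
    covs = [SubjectCovariates(bw=bw, ht=ht / 100.0, sex=sex, albumin=alb, dmsa=dmsa)
            for bw, ht, sex, alb, dmsa, _ in rows]
    return covs, [r[-1] for r in rows]


TABLE1_DURATION_DAYS = (4, 17, 7, 15, 10, 31)  # first infusion to last sample


@dataclass
class StudyDesignConfig:
    """Design of a synthetic study.

    With `covariate_source="table1"` the six study patients are used
    (n_subjects ignored); with "sampled", `n_subjects` children are drawn
    with BW ~ Uniform(bw_range) and DMSA = 0.85 * BSA(BW).
    """

    seed: int
    n_subjects: int = 6
    covariate_source: str = "table1"  # table1 | sampled
    bw_range: tuple[float, float] = (10.0, 70.0)
    male_fraction: float = 0.8
    sessions_per_week: int = 3
    session_days: tuple[int, ...] = (1, 3, 5)  # 0-based days within a week
    session_start_clock: float = 9.0  # h after midnight
    session_duration: float = 4.0  # h
    dosing_interval: float = 24.0  # h between infusions
    dose_mg_per_kg: float = 20.0
    infusion_duration: float = 0.5  # h
    duration_days: int = 7
    noise: bool = True
    samples_per_subject: int = 12

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("sessions_per_week", "session_duration", "dosing_interval",
                     "dose_mg_per_kg", "infusion_duration", "duration_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def rich_design_config(seed: int, n_subjects: int = 100) -> StudyDesignConfig:
    """The dense recovery design: q24h 20 mg/kg, 3 sessions/week, 12 samples."""
    return StudyDesignConfig(seed=seed, n_subjects=n_subjects,
                             covariate_source="sampled")


def _weekly_sessions(cfg: StudyDesignConfig, horizon: float,
                     dmsa: float | None = None) -> list[DialysisSession]:
    out = []
    week = 0
    while True:
        placed = False
        for d in cfg.session_days[: cfg.sessions_per_week]:
            start = (week * 7 + d) * 24.0 + cfg.session_start_clock
            end = start + cfg.session_duration
            if end <= horizon:
                out.append(DialysisSession(start, end, dmsa=dmsa))
                placed = True
        if not placed:
            break
        week += 1
    return out


def _sampling_times(cfg: StudyDesignConfig, infusions: Sequence[InfusionEvent],
                    sessions: Sequence[DialysisSession], horizon: float,
                    rng: np.random.Generator) -> np.ndarray:
    """TDM-style times: peaks, troughs, pre-/intra-/post-dialysis draws."""
    cand: list[float] = []
    for ev in infusions:
        cand.append(ev.end)  # end-of-infusion peak
        cand.append(ev.end + 1.0)  # early distribution point
        nxt = ev.start + cfg.dosing_interval
        if nxt < horizon:
            cand.append(nxt - 0.1)  # trough just before the next dose
    for s in sessions:
        cand.append(max(0.0, s.start - 0.25))  # pre-dialysis
        cand.append(0.5 * (s.start + s.end))  # intra-dialysis
        cand.append(s.end - 0.1)  # late intra-dialysis
        if s.end + 0.5 <= horizon:
            cand.append(s.end + 0.5)  # post-dialysis rebound window
    cand = sorted({round(t, 3) for t in cand if 0 < t <= horizon})
    if len(cand) <= cfg.samples_per_subject:
        return np.asarray(cand)
    idx = rng.choice(len(cand), size=cfg.samples_per_subject, replace=False)
    return np.asarray(cand)[np.sort(idx)]


RICH_SAMPLE_TIMES = np.array(
    [0.5, 1.5, 6.0, 23.9, 34.0, 36.9, 37.5, 48.5, 71.9, 85.5, 120.5, 167.9])
"""Fixed 12-point schedule of the recovery design (h after the first dose):
end-of-infusion and distribution points, interdialytic troughs, and
intra-/post-dialysis draws around the day-2/4/6 sessions (33-37 h etc.)."""


@dataclass
class GeneratedStudy:
    dataset: ObservationDataset
    truth: dict = field(default_factory=dict)


def generate_study(config: StudyDesignConfig, model: PopulationModel) -> GeneratedStudy:
    """Simulate a full study under `model`; returns data plus ground truth."""
    rng = np.random.default_rng(config.seed)
    if config.covariate_source == "table1":
        covs_list, _ = table1_fixture()
        horizon_days = [config.duration_days] * len(covs_list)
    elif config.covariate_source == "sampled":
        covs_list = []
        for _ in range(config.n_subjects):
            bw = rng.uniform(*config.bw_range)
            sex = "male" if rng.random() < config.male_fraction else "female"
            covs_list.append(SubjectCovariates(bw=bw, sex=sex))
        horizon_days = [config.duration_days] * len(covs_list)
    else:
        raise ValueError(f"unknown covariate_source {config.covariate_source!r}")

    names = ("cl", "v", "cldial")
    omega = np.array([model.omega.get(p, 0.0) for p in names])
    subjects, truth_rows = [], []
    for i, covs in enumerate(covs_list):
        horizon = horizon_days[i] * 24.0
        n_dose = max(1, int(np.floor((horizon - config.infusion_duration)
                                     / config.dosing_interval)) + 1)
        infusions = [InfusionEvent(j * config.dosing_interval,
                                   config.infusion_duration,
                                   config.dose_mg_per_kg * covs.bw)
                     for j in range(n_dose)]
        sessions = _weekly_sessions(config, horizon, dmsa=None)
        schedule = EventSchedule(infusions, sessions, horizon)
        if config.covariate_source == "sampled":
            times = RICH_SAMPLE_TIMES[RICH_SAMPLE_TIMES <= horizon]
        else:
            times = _sampling_times(config, infusions, sessions, horizon, rng)
        etas = dict(zip(names, rng.standard_normal(len(names)) * omega))
        params = model.individual(covs, etas)
        plan = compile_plan(schedule, times)
        pred = conc_at(plan, params)
        obs = apply_residual_error(pred, model.error, rng) if config.noise else pred
        obs = np.maximum(obs, 0.0)  # truncate for reporting; generator truth kept
        sid = f"S{i + 1:03d}"
        subjects.append(SubjectData(sid, schedule, covs, times, obs))
        truth_rows.append({
            "subject_id": sid, "etas": etas,
            "cl": params.cl_residual, "v": params.v_central,
            "cldial": params.cl_dialysis, "pred": pred.tolist(),
        })
    truth = {"seed": config.seed, "subjects": truth_rows,
             "model": {"typicals": dict(model.typicals),
                       "omega": dict(model.omega),
                       "error": {"kind": model.error.kind,
                                 "a": model.error.a, "b": model.error.b}}}
    return GeneratedStudy(ObservationDataset(subjects), truth)


def inject_outliers(dataset: ObservationDataset, k: int, magnitude: float,
                    seed: int) -> tuple[ObservationDataset, list[tuple[str, int]]]:
    """Multiply/divide `k` random observations by `magnitude`; returns flags."""
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    rng = np.random.default_rng(seed)
    index = [(i, j) for i, s in enumerate(dataset.subjects) for j in range(s.n_obs)]
    if k > len(index):
        raise ValueError("k exceeds the number of observations")
    flagged = []
    subjects = [SubjectData(s.subject_id, s.schedule, s.covariates,
                            s.obs_times.copy(), s.obs_conc.copy())
                for s in dataset.subjects]
    for pos in rng.choice(len(index), size=k, replace=False):
        i, j = index[pos]
        factor = magnitude if rng.random() < 0.5 else 1.0 / magnitude
        subjects[i].obs_conc[j] *= factor
        flagged.append((subjects[i].subject_id, j))
    return ObservationDataset(subjects, dataset.loq), flagged
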