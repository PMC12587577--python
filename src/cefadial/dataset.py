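"""In-memory observation dataset: events, covariates and concentrations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariates import SubjectCovariates
from .pk import EventSchedule, SimulationPlan, compile_plan

DEFAULT_LOQ = 0.5  # mg/L, lower end of the assay calibration range


@dataclass
class SubjectData:
    """One subject: schedule, covariates and measured total concentrations."""

    subject_id: str
    schedule: EventSchedule
    covariates: SubjectCovariates
    obs_times: np.ndarray
    obs_conc: np.ndarray
    blq: np.ndarray | None = None  # below-limit-of-quantification flags
    _plan: SimulationPlan | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.obs_conc = np.asarray(self.obs_conc, dtype=float)
        if self.obs_times.shape != self.obs_conc.shape:
            raise ValueError("obs_times and obs_conc must match in length")
        if self.obs_times.size and (
                self.obs_times.min() < -1e-9
                or self.obs_times.max() > self.schedule.horizon + 1e-9):
            raise ValueError(
                f"subject {self.subject_id}: observation outside [0, horizon]")
        if self.blq is None:
            self.blq = np.zeros(self.obs_times.shape, dtype=bool)
        self.blq = np.asarray(self.blq, dtype=bool)

    @property
    def plan(self) -> SimulationPlan:
        """Cached simulation plan at the observation times."""
        if self._plan is None:
            self._plan = compile_plan(self.schedule, self.obs_times)
        return self._plan

    @property
    def n_obs(self) -> int:
        return int(self.obs_times.size)


@dataclass
class ObservationDataset:
    subjects: list[SubjectData]
    loq: float = DEFAULT_LOQ

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def drop_blq(self) -> tuple["ObservationDataset", int]:
        """Exclude BLQ observations; returns (dataset, number dropped)."""
        dropped = 0
        subs = []
        for s in self.subjects:
            keep = ~s.blq
            dropped += int((~keep).sum())
            subs.append(SubjectData(s.subject_id, s.schedule, s.covariates,
                                    s.obs_times[keep], s.obs_conc[keep]))
        return ObservationDataset(subs, self.loq), dropped
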