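"""Hierarchical population model: log-normal BSV, residual error, likelihood.

Individual parameters are log-normal around covariate-adjusted typical
values, eta_p ~ N(0, omega_p^2) with a diagonal Omega (the published model
reports no correlations).  The residual error is additive, proportional or
combined: y = f * (1 + b*eps) + a*eps'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import covariates as cov_mod
from .covariates import CovariateEffect, SubjectCovariates, individual_structural
from .pk import EventSchedule, SimulationPlan, StructuralParams, compile_plan, conc_at

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ResidualErrorModel:
    """Residual-error model: y = f*(1 + b*eps) + a*eps'."""

    kind: str = "proportional"  # additive | proportional | combined
    a: float = 0.0  # mg/L
    b: float = 0.0  # unitless

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.a < 0 or self.b < 0:
            raise ValueError("error magnitudes must be >= 0")
        if self.a == 0 and self.b == 0:
            raise ValueError("a and b cannot both be 0")
        if self.kind == "additive" and self.b != 0:
            raise ValueError("additive model must have b = 0")
        if self.kind == "proportional" and self.a != 0:
            raise ValueError("proportional model must have a = 0")

    def sd(self, pred: np.ndarray) -> np.ndarray:
        """Standard deviation of an observation with prediction `pred`."""
        return np.sqrt(self.a ** 2 + (self.b * np.asarray(pred, dtype=float)) ** 2)


@dataclass
class PopulationModel:
    """Typical values, covariate model, Omega and residual error.

    `typicals` are {"cl", "v", "cldial"} at 70 kg / 1 m^2 DMSA; the fixed
    allometric exponents (0.75 on CL, 1 on Vd) are built in; additional
    effects (the final model's DMSA power on CLdial) live in
    `covariate_effects`.  `omega` maps parameter -> BSV standard deviation;
    an omega of 0 pins that parameter's eta at 0.
    """

    typicals: dict[str, float]
    omega: dict[str, float]
    error: ResidualErrorModel
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    fixed_exponents: dict[str, float] = field(
        default_factory=lambda: dict(cov_mod.FIXED_ALLOMETRY))
    structure: str = "1cmt"

    def __post_init__(self) -> None:
        for p, v in self.typicals.items():
            if v <= 0:
                raise ValueError(f"typical {p!r} must be > 0")
        for p, w in self.omega.items():
            if w < 0:
                raise ValueError(f"omega for {p!r} must be >= 0")

    def random_effect_names(self) -> list[str]:
        return [p for p in cov_mod.PARAM_NAMES if self.omega.get(p, 0.0) > 0]

    def individual(self, covs: SubjectCovariates,
                   etas: Mapping[str, float] | None = None) -> StructuralParams:
        return individual_structural(
            self.typicals, covs, etas, self.covariate_effects, self.fixed_exponents)


def final_published_model() -> PopulationModel:
    """The published final cefazolin model (typicals, BSV, proportional error)."""
    return PopulationModel(
        typicals=cov_mod.final_model_typicals(),
        omega={"cl": 1.07, "v": 0.197, "cldial": 0.0},
        error=ResidualErrorModel("proportional", b=0.398),
        covariate_effects=cov_mod.final_model_effects(),
    )


@dataclass
class IndividualRecord:
    covariates: SubjectCovariates
    etas: dict[str, float]
    structural: StructuralParams


def sample_individuals(
    model: PopulationModel,
    covariate_list: Sequence[SubjectCovariates],
    n_per_subject: int = 1,
    rng: np.random.Generator | int | None = None,
) -> list[IndividualRecord]:
    """Draw individuals: eta ~ N(0, diag(omega^2)), params via the covariate model."""
    rng = np.random.default_rng(rng)
    out = []
    names = list(cov_mod.PARAM_NAMES)
    sds = np.array([model.omega.get(p, 0.0) for p in names])
    for covs in covariate_list:
        for _ in range(n_per_subject):
            etas = dict(zip(names, rng.normal(0.0, 1.0, len(names)) * sds))
            out.append(IndividualRecord(covs, etas, model.individual(covs, etas)))
    return out


def apply_residual_error(
    pred: np.ndarray,
    error: ResidualErrorModel,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Perturb predictions with the residual-error model (vectorized)."""
    rng = np.random.default_rng(rng)
    pred = np.asarray(pred, dtype=float)
    y = pred.copy()
    if error.b > 0:
        y = pred * (1.0 + error.b * rng.standard_normal(pred.shape))
    if error.a > 0:
        y = y + error.a * rng.standard_normal(pred.shape)
    return y


def gaussian_loglik(obs: np.ndarray, pred: np.ndarray, error: ResidualErrorModel) -> float:
    """Sum of Normal log-densities with mean pred and sd from the error model."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sd = error.sd(pred)
    if np.any(sd <= 0) or not np.all(np.isfinite(pred)):
        return -math.inf
    z = (obs - pred) / sd
    return float(np.sum(-np.log(sd) - _LOG_SQRT_2PI - 0.5 * z * z))


def loglik_subject(
    model: PopulationModel,
    record: IndividualRecord,
    schedule: EventSchedule,
    obs_times: Sequence[float],
    obs_conc: Sequence[float],
    plan: SimulationPlan | None = None,
) -> float:
    """Observation log-likelihood of one subject given individual parameters."""
    if plan is None:
        plan = compile_plan(schedule, np.asarray(obs_times, dtype=float))
    pred = conc_at(plan, record.structural)
    return gaussian_loglik(np.asarray(obs_conc, dtype=float), pred, model.error)

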