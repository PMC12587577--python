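"""Deterministic covariate algebra for the cefazolin hemodialysis model.

Fat-free mass (Al-Sallami-type formula with sex-specific constants), body
surface area, dialysis-membrane surface area, fixed allometric body-weight
scaling, generic power/categorical covariate effects, and the final
individual-parameter equations:

    Vd_i     = 14.6  * (BW_i / 70)          * exp(eta_V)
    CL_i     = 0.186 * (BW_i / 70)^0.75     * exp(eta_CL)
    CLdial_i = 1.98  * (DMSA_i / 1)^1.26    * exp(eta_dial)

with DMSA defaulting to 0.85 * BSA(BW), BSA = (4 BW + 7) / (BW + 90).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .pk import StructuralParams

# maximum fat-free mass per height^2 (kg/m^2) and the body weight at which
# FFM is half of that maximum, by sex
WHS_MAX = {"male": 42.92, "female": 37.99}
WHS_50 = {"male": 30.93, "female": 35.98}

REFERENCE_BW = 70.0  # kg; typical values are standardized to this weight
REFERENCE_DMSA = 1.0  # m^2
DEFAULT_DMSA_COEF = 0.85  # DMSA as a fraction of BSA (recommended range 0.75-1.0)


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-subject covariates. Heights in meters, weights in kg, albumin g/L."""

    bw: float
    ht: float | None = None
    sex: str = "male"
    albumin: float | None = None
    dmsa: float | None = None
    rrt_technique: str | None = None
    vascular_access: str | None = None

    def __post_init__(self) -> None:
        if self.bw <= 0:
            raise ValueError(f"body weight must be > 0, got {self.bw}")
        if self.ht is not None and self.ht <= 0:
            raise ValueError(f"height must be > 0, got {self.ht}")
        if self.dmsa is not None and self.dmsa <= 0:
            raise ValueError(f"DMSA must be > 0, got {self.dmsa}")

    def resolved_dmsa(self, coefficient: float = DEFAULT_DMSA_COEF) -> float:
        """Subject-level DMSA, falling back to `coefficient * BSA(bw)`."""
        return self.dmsa if self.dmsa is not None else dmsa_from_bw(self.bw, coefficient)

    def value(self, name: str) -> float:
        """Covariate lookup used by generic effect evaluation."""
        if name == "dmsa":
            return self.resolved_dmsa()
        if name == "sex":
            return 0.0 if self.sex == "male" else 1.0
        v = getattr(self, name)
        if v is None:
            raise ValueError(f"covariate {name!r} missing for this subject")
        return float(v)


def fat_free_mass(bw: float, ht: float, sex: str) -> float:
    """Fat-free mass (kg) from body weight (kg), height (m) and sex."""
    if sex not in WHS_MAX:
        raise ValueError(f"unknown sex code {sex!r} (expected 'male' or 'female')")
    if bw <= 0 or ht <= 0:
        raise ValueError("bw and ht must be > 0")
    ht2 = ht * ht
    return WHS_MAX[sex] * ht2 * bw / (WHS_50[sex] * ht2 + bw)


def bsa(bw: float) -> float:
    """Body surface area (m^2) from body weight (kg): (4 BW + 7)/(BW + 90)."""
    if bw <= 0:
        raise ValueError("bw must be > 0")
    return (4.0 * bw + 7.0) / (bw + 90.0)


def dmsa_from_bw(bw: float, coefficient: float = DEFAULT_DMSA_COEF) -> float:
    """Dialysis membrane surface area (m^2) as a fraction of BSA."""
    if not (0 < coefficient <= 1.5):
        raise ValueError(f"DMSA coefficient must be in (0, 1.5], got {coefficient}")
    return coefficient * bsa(bw)


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relationship.

    Power:        theta_i = theta_pop * (cov_i / reference)^value
    Categorical:  theta_i = theta_pop * value^{cov_i}   (cov_i in {0, 1})

    `estimated` marks the coefficient as free during population fitting.
    """

    parameter: str
    covariate: str
    kind: str = "power"  # power | categorical
    value: float = 0.0
    reference: float = 1.0
    estimated: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("power", "categorical"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "power" and self.reference <= 0:
            raise ValueError("power-effect reference must be > 0")
        if self.kind == "categorical" and self.value <= 0:
            raise ValueError("categorical effect multiplier must be > 0")

    def log_term(self, covs: SubjectCovariates) -> tuple[float, float]:
        """(design value x_i, contribution value * x_i) on the log scale."""
        if self.kind == "power":
            x = math.log(covs.value(self.covariate) / self.reference)
        else:
            x = covs.value(self.covariate)
            contrib = x * math.log(self.value)
            return x, contrib
        return x, self.value * x


FIXED_ALLOMETRY = {"cl": 0.75, "v": 1.0}  # exponents on BW/70, fixed a priori

PARAM_NAMES = ("cl", "v", "cldial")


def log_fixed_offset(param: str, covs: SubjectCovariates,
                     fixed_exponents: Mapping[str, float] | None = None) -> float:
    """Built-in allometric BW term on the log scale (0 for CLdial)."""
    fixed_exponents = FIXED_ALLOMETRY if fixed_exponents is None else fixed_exponents
    beta = fixed_exponents.get(param, 0.0)
    return beta * math.log(covs.bw / REFERENCE_BW) if beta else 0.0


def individual_structural(
    typicals: Mapping[str, float],
    covs: SubjectCovariates,
    etas: Mapping[str, float] | None = None,
    effects: Sequence[CovariateEffect] = (),
    fixed_exponents: Mapping[str, float] | None = None,
) -> StructuralParams:
    """Individual structural parameters from typical values, covariates and etas.

    `typicals` holds {"cl", "v", "cldial"} (L/h, L, L/h at the reference
    covariates).  Log-normal between-subject variability enters as
    exp(eta_p); missing etas default to 0.
    """
    etas = etas or {}
    logs = {}
    for p in PARAM_NAMES:
        if typicals.get(p, 0.0) <= 0 and p != "cldial":
            raise ValueError(f"typical value for {p!r} must be > 0")
        base = typicals.get(p, 0.0)
        if base <= 0:
            logs[p] = -math.inf
            continue
        lg = math.log(base) + log_fixed_offset(p, covs, fixed_exponents)
        lg += etas.get(p, 0.0)
        logs[p] = lg
    for eff in effects:
        if eff.parameter not in logs:
            raise ValueError(f"effect targets unknown parameter {eff.parameter!r}")
        if math.isfinite(logs[eff.parameter]):
            logs[eff.parameter] += eff.log_term(covs)[1]
    return StructuralParams(
        cl_residual=math.exp(logs["cl"]),
        v_central=math.exp(logs["v"]),
        cl_dialysis=0.0 if not math.isfinite(logs["cldial"]) else math.exp(logs["cldial"]),
    )


def final_model_effects() -> list[CovariateEffect]:
    """Covariate effects of the published final model (DMSA power on CLdial)."""
    return [CovariateEffect("cldial", "dmsa", "power", 1.26, REFERENCE_DMSA)]


def final_model_typicals() -> dict[str, float]:
    """Published typical values standardized to 70 kg / 1 m^2 DMSA."""
    return {"cl": 0.186, "v": 14.6, "cldial": 1.98}
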