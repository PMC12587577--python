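import numpy as np
import pytest

from cefadial.model import (PopulationModel, ResidualErrorModel,
                            final_published_model)
from cefadial.covariates import CovariateEffect
from cefadial.synth import StudyDesignConfig, generate_study, rich_design_config


@pytest.fixture(scope="session")
def published_model():
    return final_published_model()


@pytest.fixture(scope="session")
def table1_study(published_model):
    """Six-patient study-like dataset under the published model."""
    cfg = StudyDesignConfig(seed=42)
    return generate_study(cfg, published_model)


@pytest.fixture(scope="session")
def low_noise_model():
    """Published structure with gentle variability for recovery tests."""
    return PopulationModel(
        typicals={"cl": 0.186, "v": 14.6, "cldial": 1.98},
        omega={"cl": 0.2, "v": 0.2, "cldial": 0.0},
        error=ResidualErrorModel("proportional", b=0.05),
        covariate_effects=[CovariateEffect("cldial", "dmsa", "power", 1.26)],
    )


@pytest.fixture(scope="session")
def rich_low_noise_study(low_noise_model):
    return generate_study(rich_design_config(seed=314, n_subjects=60),
                          low_noise_model)


def ode_oracle(params, schedule, times, rtol=1e-10, atol=1e-12):
    """Adaptive-step numerical integration of dC/dt = R(t)/V - k(t) C.

    Integrates segment-by-segment between breakpoints so the discontinuous
    input and clearance are handled exactly; independent of the analytic
    propagation used by the engine.
    """
    from scipy.integrate import solve_ivp

    from cefadial.pk import compile_plan

    times = np.asarray(times, dtype=float)
    plan = compile_plan(schedule, times)
    v = params.v_central
    out = np.empty(plan.grid.size)
    out[0] = c = 0.0
    for j in range(plan.seg_dt.size):
        k = (params.cl_residual + params.cl_dialysis * plan.seg_dial[j]) / v
        r = plan.seg_rate[j]
        sol = solve_ivp(lambda t, y: r / v - k * y, (0.0, plan.seg_dt[j]), [c],
                        rtol=rtol, atol=atol, method="DOP853")
        c = float(sol.y[0, -1])
        out[j + 1] = c
    return out[plan.out_idx]
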