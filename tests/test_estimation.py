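"""MAP-Bayes, marginal likelihood, SAEM fitting and the covariate step."""

import math

import numpy as np
import pytest

from cefadial.covariates import CovariateEffect, SubjectCovariates
from cefadial.dataset import ObservationDataset, SubjectData
from cefadial.estimation import (SaemSettings, covariate_step, fit_saem,
                                 map_individual, marginal_loglik)
from cefadial.model import PopulationModel, ResidualErrorModel
from cefadial.pk import (EventSchedule, InfusionEvent, DialysisSession,
                         simulate_profile)
from cefadial.synth import generate_study, rich_design_config


def _rich_subject(model, etas, subject_id="S1", bw=20.0):
    """Noise-free densely sampled subject simulated at known etas."""
    covs = SubjectCovariates(bw=bw)
    schedule = EventSchedule(
        [InfusionEvent(24 * j, 0.5, 20.0 * bw) for j in range(4)],
        [DialysisSession(33, 37), DialysisSession(81, 85)], horizon=96.0)
    times = np.concatenate([np.array([0.5, 1.0, 2.0, 6.0, 12.0, 23.9]),
                            np.array([25, 30, 34, 36, 36.9, 38, 48, 60, 71.9,
                                      82, 84.9, 86, 95])])
    params = model.individual(covs, etas)
    conc = simulate_profile(params, schedule, times).conc
    return SubjectData(subject_id, schedule, covs, times, conc)


@pytest.fixture(scope="module")
def map_model():
    return PopulationModel(
        typicals={"cl": 0.186, "v": 14.6, "cldial": 1.98},
        omega={"cl": 1.07, "v": 0.197, "cldial": 0.3},
        error=ResidualErrorModel("proportional", b=0.1),
        covariate_effects=[CovariateEffect("cldial", "dmsa", "power", 1.26)],
    )


class TestMapIndividual:
    def test_recovers_generating_etas_from_noise_free_rich_data(self, map_model):
        # a small assumed error magnitude makes the likelihood dominate the
        # prior, so the noise-free data pin the posterior mode at the truth
        model = PopulationModel(dict(map_model.typicals), dict(map_model.omega),
                                ResidualErrorModel("proportional", b=0.005),
                                list(map_model.covariate_effects))
        etas = {"cl": 0.6, "v": -0.2, "cldial": 0.15}
        subject = _rich_subject(model, etas)
        res = map_individual(model, subject)
        for p, true in etas.items():
            assert res.etas[p] == pytest.approx(true, abs=1e-4)

    def test_prior_dominates_as_omega_vanishes(self, map_model):
        etas = {"cl": 0.6, "v": -0.2, "cldial": 0.0}
        subject = _rich_subject(map_model, etas)
        tight = PopulationModel(dict(map_model.typicals),
                                {"cl": 1e-4, "v": 1e-4, "cldial": 1e-4},
                                map_model.error,
                                list(map_model.covariate_effects))
        res = map_individual(tight, subject)
        assert all(abs(v) < 1e-3 for v in res.etas.values())

    def test_single_observation_at_typical_prediction_gives_zero_eta(self,
                                                                     map_model):
        covs = SubjectCovariates(bw=20.0)
        schedule = EventSchedule([InfusionEvent(0, 0.5, 400)], [], horizon=24.0)
        pred = simulate_profile(map_model.individual(covs), schedule,
                                [23.9]).conc
        subject = SubjectData("S1", schedule, covs, [23.9], pred)
        res = map_individual(map_model, subject)
        assert all(abs(v) < 1e-5 for v in res.etas.values())

    def test_flat_prior_approaches_maximum_likelihood(self, map_model):
        etas = {"cl": 0.9, "v": 0.3, "cldial": 0.0}
        subject = _rich_subject(map_model, etas)
        flat = PopulationModel(dict(map_model.typicals),
                               {"cl": 10.0, "v": 10.0, "cldial": 10.0},
                               map_model.error, list(map_model.covariate_effects))
        res = map_individual(flat, subject)
        assert res.etas["cl"] == pytest.approx(0.9, abs=1e-3)
        assert res.etas["v"] == pytest.approx(0.3, abs=1e-3)

    def test_requires_observations(self, map_model):
        covs = SubjectCovariates(bw=20.0)
        schedule = EventSchedule([InfusionEvent(0, 0.5, 400)], [], horizon=24.0)
        subject = SubjectData("S1", schedule, covs, [], [])
        with pytest.raises(ValueError):
            map_individual(map_model, subject)


class TestMarginalLoglik:
    def test_zero_omega_reduces_to_point_likelihood(self, map_model):
        from cefadial.model import gaussian_loglik
        from cefadial.pk import compile_plan, conc_at

        subject = _rich_subject(map_model, {"cl": 0.0, "v": 0.0, "cldial": 0.0})
        point = PopulationModel(dict(map_model.typicals),
                                {"cl": 0.0, "v": 0.0, "cldial": 0.0},
                                map_model.error, list(map_model.covariate_effects))
        ds = ObservationDataset([subject])
        got = marginal_loglik(ds, point, n_is_samples=10, seed=0)
        pred = conc_at(compile_plan(subject.schedule, subject.obs_times),
                       point.individual(subject.covariates))
        assert got == pytest.approx(
            gaussian_loglik(subject.obs_conc, pred, point.error), abs=1e-10)

    def test_matches_quadrature_on_one_dimensional_toy(self):
        """Single subject, single observation, eta on CL only: the marginal
        likelihood is a 1-D integral computable by quadrature."""
        from scipy.integrate import quad
        from cefadial.model import gaussian_loglik
        from cefadial.pk import compile_plan, conc_at, StructuralParams

        model = PopulationModel(
            typicals={"cl": 0.2, "v": 10.0, "cldial": 1.0},
            omega={"cl": 0.5, "v": 0.0, "cldial": 0.0},
            error=ResidualErrorModel("proportional", b=0.2))
        covs = SubjectCovariates(bw=70.0, dmsa=1.0)
        schedule = EventSchedule([InfusionEvent(0, 1, 1000)], [], horizon=48.0)
        subject = SubjectData("S1", schedule, covs, [24.0], [55.0])
        plan = compile_plan(schedule, [24.0])

        def integrand(eta):
            p = StructuralParams(0.2 * math.exp(eta), 10.0, 1.0)
            ll = gaussian_loglik(subject.obs_conc, conc_at(plan, p), model.error)
            prior = math.exp(-0.5 * (eta / 0.5) ** 2) / (0.5 * math.sqrt(2 * math.pi))
            return math.exp(ll) * prior

        oracle = math.log(quad(integrand, -4, 4, epsabs=1e-12)[0])
        got = marginal_loglik(ObservationDataset([subject]), model,
                              n_is_samples=20_000, seed=3)
        assert got == pytest.approx(oracle, abs=5e-3)

    def test_monte_carlo_stability_across_seeds(self, map_model):
        subject = _rich_subject(map_model, {"cl": 0.3, "v": 0.1, "cldial": 0.0})
        ds = ObservationDataset([subject])
        vals = [marginal_loglik(ds, map_model, n_is_samples=1000, seed=s)
                for s in range(4)]
        assert np.std(vals) < 0.5


@pytest.fixture(scope="module")
def recovery_fit(rich_low_noise_study):
    """SAEM fit of a 60-subject low-noise rich-design dataset."""
    init = PopulationModel(
        typicals={"cl": 0.35, "v": 8.0, "cldial": 1.2},
        omega={"cl": 0.4, "v": 0.4, "cldial": 0.1},
        error=ResidualErrorModel("proportional", b=0.15),
        covariate_effects=[CovariateEffect("cldial", "dmsa", "power", 1.0,
                                           estimated=True)],
    )
    settings = SaemSettings(seed=99, n_exploration=120, n_smoothing=80,
                            compute_se=True, compute_loglik=False)
    return fit_saem(rich_low_noise_study.dataset, init, settings)


class TestSaem:
    def test_typical_values_recovered(self, recovery_fit):
        est = recovery_fit.estimates
        assert est.typicals["cl"] == pytest.approx(0.186, rel=0.07)
        assert est.typicals["v"] == pytest.approx(14.6, rel=0.07)
        assert est.typicals["cldial"] == pytest.approx(1.98, rel=0.07)
        assert est.covariate_effects[0].value == pytest.approx(1.26, rel=0.10)

    def test_variabilities_recovered(self, recovery_fit):
        est = recovery_fit.estimates
        assert est.omega["cl"] == pytest.approx(0.2, abs=0.06)
        assert est.omega["v"] == pytest.approx(0.2, abs=0.06)
        assert est.error.b == pytest.approx(0.05, abs=0.015)

    def test_standard_errors_present_and_positive(self, recovery_fit):
        for name in ("cl_pop", "v_pop", "cldial_pop", "beta_dmsa_cldial", "b"):
            assert recovery_fit.standard_errors[name] > 0
        # well-informed parameters on 60 subjects: reasonable relative SEs
        assert recovery_fit.rse_percent["v_pop"] < 25.0

    def test_deterministic_given_seed(self, rich_low_noise_study):
        init = PopulationModel(
            typicals={"cl": 0.3, "v": 10.0, "cldial": 1.5},
            omega={"cl": 0.3, "v": 0.3, "cldial": 0.1},
            error=ResidualErrorModel("proportional", b=0.1))
        small = ObservationDataset(rich_low_noise_study.dataset.subjects[:8])
        settings = SaemSettings(seed=5, n_exploration=30, n_smoothing=20,
                                compute_se=False, compute_loglik=False)
        f1 = fit_saem(small, init, settings)
        f2 = fit_saem(small, init, settings)
        assert f1.estimates.typicals == f2.estimates.typicals
        assert f1.estimates.omega == f2.estimates.omega

    def test_degenerate_bsv_shrinks_to_floor(self, low_noise_model):
        """Data simulated without BSV on Vd: the omega estimate collapses."""
        gen = PopulationModel(
            typicals=dict(low_noise_model.typicals),
            omega={"cl": 0.2, "v": 0.0, "cldial": 0.0},
            error=ResidualErrorModel("proportional", b=0.05),
            covariate_effects=list(low_noise_model.covariate_effects))
        study = generate_study(rich_design_config(seed=55, n_subjects=30), gen)
        init = PopulationModel(
            typicals={"cl": 0.3, "v": 10.0, "cldial": 1.5},
            omega={"cl": 0.3, "v": 0.3, "cldial": 0.0},
            error=ResidualErrorModel("proportional", b=0.1),
            covariate_effects=[CovariateEffect("cldial", "dmsa", "power", 1.26)])
        fit = fit_saem(study.dataset, init,
                       SaemSettings(seed=2, n_exploration=100, n_smoothing=60,
                                    compute_se=False, compute_loglik=False))
        assert fit.estimates.omega["v"] < 0.05

    def test_shrinkage_small_for_rich_design(self, recovery_fit):
        assert recovery_fit.shrinkage_percent["cl"] < 15.0
        assert recovery_fit.shrinkage_percent["v"] < 30.0

    def test_estimated_effect_requires_positive_omega(self, rich_low_noise_study):
        init = PopulationModel(
            typicals={"cl": 0.3, "v": 10.0, "cldial": 1.5},
            omega={"cl": 0.3, "v": 0.3, "cldial": 0.0},
            error=ResidualErrorModel("proportional", b=0.1),
            covariate_effects=[CovariateEffect("cldial", "dmsa", "power", 1.0,
                                               estimated=True)])
        with pytest.raises(ValueError, match="omega"):
            fit_saem(rich_low_noise_study.dataset, init,
                     SaemSettings(seed=1, n_exploration=5, n_smoothing=5))


@pytest.fixture(scope="module")
def small_study(low_noise_model):
    return generate_study(rich_design_config(seed=77, n_subjects=20),
                          low_noise_model)


class TestCovariateStep:
    def test_true_covariate_retained(self, small_study):
        """Data carry a DMSA effect on CLdial; the forward step keeps it."""
        base = PopulationModel(
            typicals={"cl": 0.2, "v": 12.0, "cldial": 1.5},
            omega={"cl": 0.3, "v": 0.3, "cldial": 0.3},
            error=ResidualErrorModel("proportional", b=0.1))
        settings = SaemSettings(seed=8, n_exploration=80, n_smoothing=50,
                                compute_se=False, n_is_samples=300)
        base_fit = fit_saem(small_study.dataset, base, settings)
        res = covariate_step(small_study.dataset, base_fit,
                             CovariateEffect("cldial", "dmsa", "power", 1.0),
                             settings)
        assert res.retained
        assert res.delta_bic < 0
        assert res.delta_bsv < 0
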