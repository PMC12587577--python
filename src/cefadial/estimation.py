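"""Population and individual parameter inference.

``fit_saem`` implements stochastic approximation expectation-maximization
for the log-normal one-compartment model: the E-step runs per-subject
Metropolis-Hastings kernels on the random effects (an independence proposal
from the prior, a joint random walk, and componentwise random walks, with
Robbins-Monro scale adaptation); the SA step accumulates sufficient
statistics with step 1 during exploration and 1/(k - k0) during smoothing;
the M-step is a closed-form weighted regression on the log scale for
typical values and covariate coefficients, with closed-form updates for the
omegas and the residual-error magnitude.  Typical values are estimated on
the log scale, which enforces positivity.

``map_individual`` is the MAP-Bayes estimator used for therapeutic drug
monitoring: the posterior mode of a subject's etas given sparse
concentrations and the population priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .covariates import PARAM_NAMES, CovariateEffect, log_fixed_offset
from .dataset import ObservationDataset, SubjectData
from .model import PopulationModel, ResidualErrorModel, gaussian_loglik
from .pk import StructuralParams, _propagate

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Subject working structure
# ---------------------------------------------------------------------------


@dataclass
class _Work:
    """Pre-resolved per-subject quantities reused across likelihood calls."""

    y: np.ndarray
    seg_dt: np.ndarray
    seg_rate: np.ndarray
    seg_dial: np.ndarray
    out_idx: np.ndarray
    fixed_off: np.ndarray  # per param: allometric + non-estimated effect log terms
    g: list[np.ndarray]  # per param: [1, x_estimated_effects...]

    def predict(self, log_phi: np.ndarray) -> np.ndarray:
        cl, v, cldial = np.exp(log_phi)
        k = (cl + cldial * self.seg_dial) / v
        return _propagate(self.seg_dt, self.seg_rate, k, v, 0.0)[self.out_idx]


def _build_work(subject: SubjectData, model: PopulationModel) -> _Work:
    plan = subject.plan
    fixed_off = np.zeros(3)
    g = []
    for pi, p in enumerate(PARAM_NAMES):
        fixed_off[pi] = log_fixed_offset(p, subject.covariates, model.fixed_exponents)
        xs = [1.0]
        for eff in model.covariate_effects:
            if eff.parameter != p:
                continue
            x, contrib = eff.log_term(subject.covariates)
            if eff.estimated:
                xs.append(x)
            else:
                fixed_off[pi] += contrib
        g.append(np.asarray(xs))
    return _Work(subject.obs_conc.astype(float), plan.seg_dt, plan.seg_rate,
                 plan.seg_dial, plan.out_idx, fixed_off, g)


def _coef_vectors(model: PopulationModel) -> list[np.ndarray]:
    """Per param: [log typical, estimated-effect coefficients (log scale)]."""
    out = []
    for p in PARAM_NAMES:
        c = [math.log(model.typicals[p])]
        for eff in model.covariate_effects:
            if eff.parameter == p and eff.estimated:
                c.append(eff.value if eff.kind == "power" else math.log(eff.value))
        out.append(np.asarray(c))
    return out


def _install_coefs(model: PopulationModel, coefs: list[np.ndarray]) -> None:
    for pi, p in enumerate(PARAM_NAMES):
        model.typicals[p] = math.exp(coefs[pi][0])
        j = 1
        for ei, eff in enumerate(model.covariate_effects):
            if eff.parameter == p and eff.estimated:
                val = coefs[pi][j] if eff.kind == "power" else math.exp(coefs[pi][j])
                model.covariate_effects[ei] = replace(eff, value=val)
                j += 1


def _obs_loglik(y: np.ndarray, pred: np.ndarray, error: ResidualErrorModel) -> float:
    return gaussian_loglik(y, pred, error)


# ---------------------------------------------------------------------------
# MAP-Bayes individual estimation
# ---------------------------------------------------------------------------


@dataclass
class MapResult:
    etas: dict[str, float]
    structural: StructuralParams
    predictions: np.ndarray
    neg_log_posterior: float
    converged: bool


def map_individual(model: PopulationModel, subject: SubjectData,
                   max_restarts: int = 3, seed: int = 0) -> MapResult:
    """Posterior-mode etas for one subject under the population priors.

    Minimizes the iteratively reweighted MAP objective

        1/2 sum_j ((y_j - f_j(eta)) / sd_j)^2 + 1/2 eta' diag(omega^2)^-1 eta

    by L-BFGS-B, where the residual standard deviations sd_j are evaluated
    at the predictions of the previous sweep and held fixed within each
    sweep (classical MAP weighting: no log-variance term).  Noise-free data
    therefore recover their generating etas exactly, and an observation
    equal to the typical prediction leaves the posterior mode at the prior
    mode.  Random restarts from the prior are used on non-convergence.
    """
    if subject.n_obs < 1:
        raise ValueError("MAP estimation needs at least one observation")
    work = _build_work(subject, model)
    coefs = _coef_vectors(model)
    base_log = np.array([work.fixed_off[pi] + work.g[pi] @ coefs[pi]
                         for pi in range(3)])
    free = [pi for pi, p in enumerate(PARAM_NAMES) if model.omega.get(p, 0.0) > 0]
    omega = np.array([model.omega[PARAM_NAMES[pi]] for pi in free])

    def solve_at_weights(sd: np.ndarray, x0: np.ndarray):
        def objective(eta_free: np.ndarray) -> float:
            log_phi = base_log.copy()
            log_phi[free] += eta_free
            pred = work.predict(log_phi)
            if not np.all(np.isfinite(pred)):
                return 1e12
            wss = 0.5 * float(np.sum(((work.y - pred) / sd) ** 2))
            return wss + 0.5 * float(np.sum((eta_free / omega) ** 2))

        return minimize(objective, x0, method="L-BFGS-B",
                        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500})

    rng = np.random.default_rng(seed)
    best, converged = None, False
    x0 = np.zeros(len(free))
    for attempt in range(max_restarts + 1):
        # IRLS sweeps: weights from the typical prediction, then refined at
        # the fitted individual predictions (floored to avoid zero variance)
        pred = work.predict(base_log)
        res = None
        for _ in range(3):
            sd = model.error.sd(np.maximum(pred, 0.5))
            res = solve_at_weights(sd, res.x if res is not None else x0)
            log_phi = base_log.copy()
            log_phi[free] += res.x
            pred = work.predict(log_phi)
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            converged = True
            break
        x0 = rng.normal(0.0, 1.0, len(free)) * omega
    etas = {p: 0.0 for p in PARAM_NAMES}
    for j, pi in enumerate(free):
        etas[PARAM_NAMES[pi]] = float(best.x[j])
    log_phi = base_log.copy()
    log_phi[free] += best.x
    structural = StructuralParams(cl_residual=float(np.exp(log_phi[0])),
                                  v_central=float(np.exp(log_phi[1])),
                                  cl_dialysis=float(np.exp(log_phi[2])))
    return MapResult(etas, structural, work.predict(log_phi), float(best.fun),
                     converged)


# ---------------------------------------------------------------------------
# Marginal likelihood by importance sampling
# ---------------------------------------------------------------------------


def marginal_loglik(dataset: ObservationDataset, model: PopulationModel,
                    n_is_samples: int = 1000, seed: int = 0,
                    ess_warn: float = 20.0) -> float:
    """Importance-sampling estimate of the marginal observation log-likelihood.

    The proposal is a multivariate t (df 4) centered at each subject's MAP
    eta with scale from the numerical Hessian of the negative log posterior.
    With all omegas 0 this reduces exactly to the likelihood at eta = 0.
    """
    rng = np.random.default_rng(seed)
    total = 0.0
    df = 4.0
    for si, subject in enumerate(dataset.subjects):
        work = _build_work(subject, model)
        coefs = _coef_vectors(model)
        base_log = np.array([work.fixed_off[pi] + work.g[pi] @ coefs[pi]
                             for pi in range(3)])
        free = [pi for pi, p in enumerate(PARAM_NAMES)
                if model.omega.get(p, 0.0) > 0]
        if not free:
            total += _obs_loglik(work.y, work.predict(base_log), model.error)
            continue
        omega = np.array([model.omega[PARAM_NAMES[pi]] for pi in free])
        mp = map_individual(model, subject, seed=seed + si)
        center = np.array([mp.etas[PARAM_NAMES[pi]] for pi in free])

        def nlp(eta_free: np.ndarray) -> float:
            log_phi = base_log.copy()
            log_phi[free] += eta_free
            ll = _obs_loglik(work.y, work.predict(log_phi), model.error)
            return -ll + 0.5 * float(np.sum((eta_free / omega) ** 2))

        d = len(free)
        h = np.zeros((d, d))
        eps = 1e-3
        f0 = nlp(center)
        for a in range(d):
            for b in range(a, d):
                ea, eb = np.zeros(d), np.zeros(d)
                ea[a], eb[b] = eps, eps
                h[a, b] = h[b, a] = (nlp(center + ea + eb) - nlp(center + ea)
                                     - nlp(center + eb) + f0) / eps ** 2
        h = 0.5 * (h + h.T) + 1e-6 * np.eye(d)
        try:
            cov = np.linalg.inv(h)
            chol = np.linalg.cholesky(0.5 * (cov + cov.T))
        except np.linalg.LinAlgError:
            chol = np.diag(omega)
        z = rng.standard_normal((n_is_samples, d))
        u = rng.chisquare(df, n_is_samples)
        t = z * np.sqrt(df / u)[:, None]
        etas = center + t @ chol.T
        # log density of the multivariate t proposal
        logdet = float(np.sum(np.log(np.diag(chol))))
        quad = np.sum(np.linalg.solve(chol, (etas - center).T) ** 2, axis=0)
        log_q = (math.lgamma((df + d) / 2) - math.lgamma(df / 2)
                 - 0.5 * d * math.log(df * math.pi) - logdet
                 - 0.5 * (df + d) * np.log1p(quad / df))
        log_w = np.empty(n_is_samples)
        for m in range(n_is_samples):
            log_phi = base_log.copy()
            log_phi[free] += etas[m]
            ll = _obs_loglik(work.y, work.predict(log_phi), model.error)
            lp = (-0.5 * np.sum((etas[m] / omega) ** 2)
                  - np.sum(np.log(omega)) - d * _LOG_SQRT_2PI)
            log_w[m] = ll + lp - log_q[m]
        total += float(logsumexp(log_w) - math.log(n_is_samples))
        ess = float(np.exp(2 * logsumexp(log_w) - logsumexp(2 * log_w)))
        if ess < ess_warn:
            import warnings

            warnings.warn(f"subject {subject.subject_id}: IS effective sample "
                          f"size {ess:.1f} below {ess_warn}")
    return total


def bic(loglik: float, n_subject_level: int, n_obs_level: int,
        n_subjects: int, n_obs: int) -> float:
    """Mixed-level BIC: subject-level parameters penalized by log(N_subjects),
    residual-error parameters by log(N_observations)."""
    return (-2.0 * loglik + n_subject_level * math.log(n_subjects)
            + n_obs_level * math.log(n_obs))


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------


@dataclass
class SaemSettings:
    """SAEM run configuration.

    Defaults follow common practice for sparse pediatric datasets: several
    Markov chains when fewer than 30 subjects, 300 exploration iterations
    with step 1 (with simulated-annealing floors on the variances) then 200
    smoothing iterations with step 1/(k - k0).
    """

    seed: int
    n_exploration: int = 300
    n_smoothing: int = 200
    n_chains: int | None = None  # auto: 5 below 30 subjects, else 1
    omega_floor: float = 0.02
    anneal: float = 0.95
    n_is_samples: int = 500
    n_se_draws: int = 200
    compute_se: bool = True
    compute_loglik: bool = True


@dataclass
class FitResult:
    estimates: PopulationModel
    loglik: float
    bic: float
    standard_errors: dict[str, float]
    rse_percent: dict[str, float]
    ebes: pd.DataFrame
    shrinkage_percent: dict[str, float]
    trace: pd.DataFrame
    converged: bool
    settings: SaemSettings = field(repr=False, default=None)

    def parameter_table(self) -> pd.DataFrame:
        """Estimate / RSE% / shrinkage% table in the conventional layout."""
        rows = []
        m = self.estimates
        for p in PARAM_NAMES:
            name = f"{p}_pop"
            rows.append((name, m.typicals[p], self.rse_percent.get(name),
                         None))
        for eff in m.covariate_effects:
            name = f"beta_{eff.covariate}_{eff.parameter}"
            rows.append((name, eff.value,
                         self.rse_percent.get(name) if eff.estimated else None,
                         None))
        for p in PARAM_NAMES:
            if m.omega.get(p, 0.0) > 0:
                name = f"omega_{p}"
                rows.append((name, m.omega[p], self.rse_percent.get(name),
                             self.shrinkage_percent.get(p)))
        if m.error.a > 0:
            rows.append(("a", m.error.a, self.rse_percent.get("a"), None))
        if m.error.b > 0:
            rows.append(("b", m.error.b, self.rse_percent.get("b"), None))
        return pd.DataFrame(rows, columns=["parameter", "estimate",
                                           "rse_percent", "shrinkage_percent"])


class SaemDivergence(RuntimeError):
    def __init__(self, message: str, trace: pd.DataFrame):
        super().__init__(message)
        self.trace = trace


def fit_saem(dataset: ObservationDataset, initial_model: PopulationModel,
             settings: SaemSettings) -> FitResult:
    """Maximum-likelihood population fit by SAEM.

    All typical values are estimated (on the log scale), along with the
    coefficients of covariate effects flagged ``estimated``, the omegas of
    parameters whose initial omega is positive, and the residual-error
    magnitude(s).  A parameter carrying estimated coefficients must have a
    positive initial omega so the regression M-step is defined; omegas are
    floored at ``settings.omega_floor``.
    """
    model = PopulationModel(dict(initial_model.typicals), dict(initial_model.omega),
                            initial_model.error,
                            [replace(e) for e in initial_model.covariate_effects],
                            dict(initial_model.fixed_exponents),
                            initial_model.structure)
    n = dataset.n_subjects
    n_chains = settings.n_chains or (5 if n < 30 else 1)
    rng = np.random.default_rng(settings.seed)
    works = [_build_work(s, model) for s in dataset.subjects]
    if not any(s.schedule.sessions for s in dataset.subjects) and \
            model.typicals.get("cldial", 0) > 0:
        import warnings

        warnings.warn("no dialysis sessions in the dataset: CLdial is not "
                      "identifiable from these data")

    coefs = _coef_vectors(model)
    omega = np.array([model.omega.get(p, 0.0) for p in PARAM_NAMES])
    est_omega = omega > 0
    for pi, p in enumerate(PARAM_NAMES):
        if len(coefs[pi]) > 1 and omega[pi] <= 0:
            raise ValueError(f"{p}: estimated covariate coefficients require a "
                             "positive initial omega")
    free = np.where(est_omega)[0]
    error = model.error
    a2, b2 = error.a ** 2, error.b ** 2

    # H matrices of the log-scale regressions (constant across iterations)
    H = [np.mean([np.outer(w.g[pi], w.g[pi]) for w in works], axis=0)
         for pi in range(3)]

    n_iter = settings.n_exploration + settings.n_smoothing
    eta = np.zeros((n_chains, n, 3))
    ll = np.full((n_chains, n), -np.inf)
    preds = [[None] * n for _ in range(n_chains)]
    s_joint, s_comp = 0.4, np.full(3, 0.4)
    T1 = [np.zeros_like(coefs[pi]) for pi in range(3)]
    T2 = np.zeros(3)
    Terr = 0.0
    trace_rows = []

    def log_phi_of(i: int, e: np.ndarray) -> np.ndarray:
        w = works[i]
        return np.array([w.fixed_off[pi] + w.g[pi] @ coefs[pi] + e[pi]
                         for pi in range(3)])

    def obs_ll(i: int, e: np.ndarray) -> tuple[float, np.ndarray]:
        pred = works[i].predict(log_phi_of(i, e))
        return _obs_loglik(works[i].y, pred, error), pred

    for it in range(n_iter):
        exploring = it < settings.n_exploration
        gamma = 1.0 if exploring else 1.0 / (it - settings.n_exploration + 1)
        acc_joint = np.zeros(2)
        acc_comp = np.zeros((3, 2))
        for c in range(n_chains):
            for i in range(n):
                ll[c, i], preds[c][i] = obs_ll(i, eta[c, i])
                # kernel 1: independence proposal from the prior
                e_new = np.zeros(3)
                e_new[free] = rng.standard_normal(free.size) * omega[free]
                ll_new, pred_new = obs_ll(i, e_new)
                if math.log(rng.random()) < ll_new - ll[c, i]:
                    eta[c, i], ll[c, i], preds[c][i] = e_new, ll_new, pred_new
                # kernel 2: joint random walk
                e_new = eta[c, i].copy()
                e_new[free] += s_joint * omega[free] * rng.standard_normal(free.size)
                ll_new, pred_new = obs_ll(i, e_new)
                dprior = -0.5 * np.sum(((e_new[free] ** 2 - eta[c, i][free] ** 2)
                                        / omega[free] ** 2))
                acc_joint[1] += 1
                if math.log(rng.random()) < ll_new - ll[c, i] + dprior:
                    eta[c, i], ll[c, i], preds[c][i] = e_new, ll_new, pred_new
                    acc_joint[0] += 1
                # kernel 3: componentwise random walk
                for pi in free:
                    e_new = eta[c, i].copy()
                    e_new[pi] += s_comp[pi] * omega[pi] * rng.standard_normal()
                    ll_new, pred_new = obs_ll(i, e_new)
                    dprior = -0.5 * ((e_new[pi] ** 2 - eta[c, i][pi] ** 2)
                                     / omega[pi] ** 2)
                    acc_comp[pi, 1] += 1
                    if math.log(rng.random()) < ll_new - ll[c, i] + dprior:
                        eta[c, i], ll[c, i], preds[c][i] = e_new, ll_new, pred_new
                        acc_comp[pi, 0] += 1
        if not np.all(np.isfinite(ll)):
            raise SaemDivergence("non-finite log-likelihood during SAEM",
                                 pd.DataFrame(trace_rows))
        if exploring:  # Robbins-Monro proposal-scale adaptation
            step = 1.0 / math.sqrt(it + 1.0)
            rate = acc_joint[0] / max(acc_joint[1], 1)
            s_joint *= math.exp(step * (rate - 0.3))
            for pi in free:
                rate = acc_comp[pi, 0] / max(acc_comp[pi, 1], 1)
                s_comp[pi] *= math.exp(step * (rate - 0.4))

        # sufficient statistics (averaged over subjects and chains)
        stat1 = [np.zeros_like(coefs[pi]) for pi in range(3)]
        stat2 = np.zeros(3)
        stat_err, n_err = 0.0, 0
        for c in range(n_chains):
            for i in range(n):
                w = works[i]
                for pi in range(3):
                    z = w.g[pi] @ coefs[pi] + eta[c, i, pi]
                    stat1[pi] += w.g[pi] * z
                    stat2[pi] += z * z
                r = w.y - preds[c][i]
                if error.kind == "proportional":
                    stat_err += float(np.sum((r / preds[c][i]) ** 2))
                elif error.kind == "additive":
                    stat_err += float(np.sum(r ** 2))
                else:  # combined: approximate via current variance weights
                    sd2 = a2 + b2 * preds[c][i] ** 2
                    stat_err += float(np.sum(r ** 2 / sd2))
                n_err += w.y.size
        denom = n * n_chains
        for pi in range(3):
            T1[pi] += gamma * (stat1[pi] / denom - T1[pi])
        T2 += gamma * (stat2 / denom - T2)
        Terr += gamma * (stat_err / n_err - Terr)

        # M-step
        for pi in range(3):
            try:
                coefs[pi] = np.linalg.solve(H[pi], T1[pi])
            except np.linalg.LinAlgError:
                coefs[pi] = np.linalg.lstsq(H[pi], T1[pi], rcond=None)[0]
            if est_omega[pi]:
                var = T2[pi] - 2 * coefs[pi] @ T1[pi] + coefs[pi] @ H[pi] @ coefs[pi]
                var = max(var, settings.omega_floor ** 2)
                if exploring:
                    var = max(var, settings.anneal * omega[pi] ** 2)
                omega[pi] = math.sqrt(var)
        if error.kind == "proportional":
            new_b2 = max(Terr, 1e-8)
            if exploring:
                new_b2 = max(new_b2, settings.anneal * b2)
            b2 = new_b2
            error = ResidualErrorModel("proportional", b=math.sqrt(b2))
        elif error.kind == "additive":
            new_a2 = max(Terr, 1e-8)
            if exploring:
                new_a2 = max(new_a2, settings.anneal * a2)
            a2 = new_a2
            error = ResidualErrorModel("additive", a=math.sqrt(a2))
        else:
            scale = max(Terr, 1e-8)  # joint rescale of (a, b) by fitted weights
            a2, b2 = a2 * scale, b2 * scale
            error = ResidualErrorModel("combined", a=math.sqrt(a2), b=math.sqrt(b2))

        row = {"iteration": it, "phase": "exploration" if exploring else "smoothing"}
        for pi, p in enumerate(PARAM_NAMES):
            row[f"{p}_pop"] = math.exp(coefs[pi][0])
            row[f"omega_{p}"] = omega[pi]
            for j in range(1, len(coefs[pi])):
                row[f"{p}_coef{j}"] = coefs[pi][j]
        row["a"], row["b"] = error.a, error.b
        trace_rows.append(row)

    _install_coefs(model, coefs)
    for pi, p in enumerate(PARAM_NAMES):
        model.omega[p] = float(omega[pi]) if est_omega[pi] else model.omega.get(p, 0.0)
    model.error = error
    trace = pd.DataFrame(trace_rows)

    # EBEs, shrinkage
    ebe_rows = []
    for subject in dataset.subjects:
        mp = map_individual(model, subject, seed=settings.seed)
        row = {"subject_id": subject.subject_id}
        for p in PARAM_NAMES:
            row[f"eta_{p}"] = mp.etas[p]
        row.update(cl=mp.structural.cl_residual, v=mp.structural.v_central,
                   cldial=mp.structural.cl_dialysis)
        ebe_rows.append(row)
    ebes = pd.DataFrame(ebe_rows)
    shr = {}
    for pi, p in enumerate(PARAM_NAMES):
        if est_omega[pi]:
            sd_ebe = float(ebes[f"eta_{p}"].std(ddof=1)) if n > 1 else 0.0
            shr[p] = 100.0 * (1.0 - sd_ebe / omega[pi])

    # standard errors: empirical Fisher from posterior-mean scores
    ses: dict[str, float] = {}
    if settings.compute_se:
        ses = _empirical_fisher_se(works, dataset, model, coefs, omega, est_omega,
                                   error, eta[0], settings, rng)
    names_map = _parameter_names(model)
    rse = {}
    values = _parameter_values(model)
    for name in names_map:
        if name in ses and values[name]:
            rse[name] = 100.0 * ses[name] / abs(values[name])

    loglik = float("nan")
    bic_val = float("nan")
    if settings.compute_loglik:
        loglik = marginal_loglik(dataset, model, settings.n_is_samples,
                                 settings.seed + 1)
        n_subject_level = (sum(len(c) for c in coefs) + int(est_omega.sum()))
        n_obs_level = (1 if error.kind != "combined" else 2)
        bic_val = bic(loglik, n_subject_level, n_obs_level, n, dataset.n_obs)

    return FitResult(model, loglik, bic_val, ses, rse, ebes, shr, trace,
                     converged=True, settings=settings)


def _parameter_names(model: PopulationModel) -> list[str]:
    names = [f"{p}_pop" for p in PARAM_NAMES]
    names += [f"beta_{e.covariate}_{e.parameter}"
              for e in model.covariate_effects if e.estimated]
    names += [f"omega_{p}" for p in PARAM_NAMES if model.omega.get(p, 0.0) > 0]
    if model.error.a > 0:
        names.append("a")
    if model.error.b > 0:
        names.append("b")
    return names


def _parameter_values(model: PopulationModel) -> dict[str, float]:
    vals = {f"{p}_pop": model.typicals[p] for p in PARAM_NAMES}
    for e in model.covariate_effects:
        if e.estimated:
            vals[f"beta_{e.covariate}_{e.parameter}"] = e.value
    for p in PARAM_NAMES:
        if model.omega.get(p, 0.0) > 0:
            vals[f"omega_{p}"] = model.omega[p]
    vals["a"], vals["b"] = model.error.a, model.error.b
    return vals


def _empirical_fisher_se(works, dataset, model, coefs, omega, est_omega, error,
                         eta0, settings, rng) -> dict[str, float]:
    """SEs from the outer product of per-subject posterior-mean scores.

    By the Fisher identity the marginal score of subject i is the posterior
    expectation of the complete-data score; the information matrix is
    approximated by the sum of outer products over subjects, with the
    expectation taken over post-convergence MH draws.
    """
    n = len(works)
    free = np.where(est_omega)[0]
    # layout: per param (coef vector), then omegas (free), then error magnitude(s)
    blocks, names = [], []
    for pi, p in enumerate(PARAM_NAMES):
        blocks.append(len(coefs[pi]))
        names.append(f"{p}_pop")
        j = 0
        for e in model.covariate_effects:
            if e.parameter == p and e.estimated:
                j += 1
                names.append(f"beta_{e.covariate}_{e.parameter}")
    for pi in free:
        names.append(f"omega_{PARAM_NAMES[pi]}")
    err_names = (["a"] if error.a > 0 else []) + (["b"] if error.b > 0 else [])
    names += err_names
    dim = sum(blocks) + free.size + len(err_names)
    score_sum = np.zeros((n, dim))
    eta = eta0.copy()
    n_draws = settings.n_se_draws
    for _ in range(n_draws):
        for i in range(n):
            w = works[i]
            # one joint RW move per draw keeps the chain mixing cheaply
            e_new = eta[i].copy()
            e_new[free] += 0.4 * omega[free] * rng.standard_normal(free.size)
            lp_old = np.array([w.fixed_off[pi] + w.g[pi] @ coefs[pi] + eta[i][pi]
                               for pi in range(3)])
            lp_new = lp_old + (e_new - eta[i])
            ll_old = _obs_loglik(w.y, w.predict(lp_old), error)
            ll_new = _obs_loglik(w.y, w.predict(lp_new), error)
            dprior = -0.5 * np.sum((e_new[free] ** 2 - eta[i][free] ** 2)
                                   / omega[free] ** 2)
            if math.log(rng.random()) < ll_new - ll_old + dprior:
                eta[i] = e_new
            s = np.zeros(dim)
            off = 0
            for pi in range(3):
                nb = blocks[pi]
                if est_omega[pi]:
                    s[off:off + nb] = w.g[pi] * eta[i][pi] / omega[pi] ** 2
                off += nb
            for jj, pi in enumerate(free):
                s[sum(blocks) + jj] = (-1.0 / omega[pi]
                                       + eta[i][pi] ** 2 / omega[pi] ** 3)
            pred = w.predict(np.array([w.fixed_off[pi] + w.g[pi] @ coefs[pi]
                                       + eta[i][pi] for pi in range(3)]))
            r = w.y - pred
            base = sum(blocks) + free.size
            sd2 = error.a ** 2 + (error.b * pred) ** 2
            kk = 0
            if error.a > 0:
                s[base + kk] = float(np.sum(-error.a / sd2 + error.a * r ** 2 / sd2 ** 2))
                kk += 1
            if error.b > 0:
                s[base + kk] = float(np.sum(-error.b * pred ** 2 / sd2
                                            + error.b * pred ** 2 * r ** 2 / sd2 ** 2))
            score_sum[i] += s
    sbar = score_sum / n_draws
    info = sbar.T @ sbar
    try:
        cov = np.linalg.inv(info + 1e-10 * np.eye(dim))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return dict(zip(names, se.tolist()))


def shrinkage(fit: FitResult) -> dict[str, float]:
    """Eta-shrinkage, 100*(1 - sd(EBE)/omega), per estimated random effect."""
    return dict(fit.shrinkage_percent)


@dataclass
class CovariateStepResult:
    delta_bic: float
    delta_bsv: float
    retained: bool
    candidate_fit: FitResult


def covariate_step(dataset: ObservationDataset, base_fit: FitResult,
                   candidate: CovariateEffect,
                   settings: SaemSettings) -> CovariateStepResult:
    """Forward covariate step: refit with the candidate effect added.

    Retained iff the BIC decreases AND the BSV (omega) of the affected
    parameter decreases — the published retention rule.
    """
    base = base_fit.estimates
    if candidate.parameter not in PARAM_NAMES:
        raise ValueError(f"candidate targets unknown parameter {candidate.parameter!r}")
    cand_model = PopulationModel(dict(base.typicals), dict(base.omega),
                                 base.error,
                                 [replace(e) for e in base.covariate_effects]
                                 + [replace(candidate, estimated=True)],
                                 dict(base.fixed_exponents), base.structure)
    if cand_model.omega.get(candidate.parameter, 0.0) <= 0:
        cand_model.omega[candidate.parameter] = 0.1
    fit = fit_saem(dataset, cand_model, settings)
    delta_bic = fit.bic - base_fit.bic
    delta_bsv = (fit.estimates.omega.get(candidate.parameter, 0.0)
                 - base.omega.get(candidate.parameter, 0.0))
    return CovariateStepResult(delta_bic, delta_bsv,
                               retained=delta_bic < 0 and delta_bsv < 0,
                               candidate_fit=fit)
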