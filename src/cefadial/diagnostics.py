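"""Simulation-based model diagnostics: NPDE, pc-VPC, goodness-of-fit tables.

NPDE (normalized prediction distribution errors) simulates each subject's
observation vector many times under the model (BSV + residual error),
decorrelates observed and simulated vectors with the inverse Cholesky
factor of the empirical simulation covariance, converts the rank of each
decorrelated observation among its simulations to a probability, and maps
it through the standard-normal quantile.  Under a correct model the NPDE
are iid N(0, 1): the attached tests check mean 0 (one-sample t), variance 1
(chi-square) and normality (Shapiro-Wilk).

The prediction-corrected VPC normalizes observed and simulated values by
the ratio of the bin-median population prediction to each point's own
population prediction, bins on time after last dose, and compares observed
5/50/95th percentiles with 90% confidence bands of the simulated ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import PARAM_NAMES
from .dataset import ObservationDataset, SubjectData
from .estimation import FitResult, _build_work, _coef_vectors, map_individual
from .model import PopulationModel, apply_residual_error


def _pred_at_etas(subject: SubjectData, model: PopulationModel,
                  eta: np.ndarray) -> np.ndarray:
    work = _build_work(subject, model)
    coefs = _coef_vectors(model)
    log_phi = np.array([work.fixed_off[pi] + work.g[pi] @ coefs[pi] + eta[pi]
                        for pi in range(3)])
    return work.predict(log_phi)


def _simulate_replicates(subject: SubjectData, model: PopulationModel,
                         k: int, rng: np.random.Generator) -> np.ndarray:
    """k simulated observation vectors (k x n_obs) under BSV + residual error."""
    omega = np.array([model.omega.get(p, 0.0) for p in PARAM_NAMES])
    work = _build_work(subject, model)
    coefs = _coef_vectors(model)
    base_log = np.array([work.fixed_off[pi] + work.g[pi] @ coefs[pi]
                         for pi in range(3)])
    out = np.empty((k, subject.n_obs))
    for m in range(k):
        eta = rng.standard_normal(3) * omega
        pred = work.predict(base_log + eta)
        out[m] = apply_residual_error(pred, model.error, rng)
    return out


@dataclass
class NpdeResult:
    table: pd.DataFrame  # subject_id, time, observed, npde
    mean_pvalue: float
    variance_pvalue: float
    normality_pvalue: float

    @property
    def npde(self) -> np.ndarray:
        return self.table["npde"].to_numpy()


def npde(dataset: ObservationDataset, model: PopulationModel, k_sim: int = 500,
         seed: int = 0) -> NpdeResult:
    """Normalized prediction distribution errors with the three summary tests."""
    if k_sim < 100:
        raise ValueError("k_sim must be at least 100")
    rng = np.random.default_rng(seed)
    rows = []
    for subject in dataset.subjects:
        sims = _simulate_replicates(subject, model, k_sim, rng)
        mu = sims.mean(axis=0)
        cov = np.cov(sims, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn(f"subject {subject.subject_id}: singular simulation "
                          "covariance, ridge-regularizing")
            chol = np.linalg.cholesky(cov + 1e-8 * np.trace(cov)
                                      / cov.shape[0] * np.eye(cov.shape[0]))
        dec_obs = np.linalg.solve(chol, subject.obs_conc - mu)
        dec_sim = np.linalg.solve(chol, (sims - mu).T)  # n_obs x k
        pde = (dec_sim < dec_obs[:, None]).mean(axis=1)
        pde = np.clip(pde, 1.0 / (2 * k_sim), 1.0 - 1.0 / (2 * k_sim))
        vals = stats.norm.ppf(pde)
        for t, y, v in zip(subject.obs_times, subject.obs_conc, vals):
            rows.append((subject.subject_id, t, y, v))
    table = pd.DataFrame(rows, columns=["subject_id", "time", "observed", "npde"])
    x = table["npde"].to_numpy()
    n = x.size
    p_mean = float(stats.ttest_1samp(x, 0.0).pvalue)
    chi2_stat = (n - 1) * np.var(x, ddof=1)
    p_var = float(2 * min(stats.chi2.cdf(chi2_stat, n - 1),
                          stats.chi2.sf(chi2_stat, n - 1)))
    p_norm = float(stats.shapiro(x).pvalue)
    return NpdeResult(table, p_mean, p_var, p_norm)


@dataclass
class VpcResult:
    bins: pd.DataFrame
    """Per bin: edges, n, observed 5/50/95th percentiles, and the 90% CI
    (lo/hi) of the simulated percentiles."""
    n_sim: int = 0

    def observed_within_bands(self) -> float:
        """Fraction of (bin, percentile) cells with the observed value inside
        the simulated 90% band."""
        ok, total = 0, 0
        for q in (5, 50, 95):
            obs = self.bins[f"obs_p{q}"]
            lo, hi = self.bins[f"sim_p{q}_lo"], self.bins[f"sim_p{q}_hi"]
            ok += int(((obs >= lo) & (obs <= hi)).sum())
            total += len(obs)
        return ok / total


def _time_after_last_dose(subject: SubjectData) -> np.ndarray:
    starts = np.array([ev.start for ev in subject.schedule.infusions])
    tald = np.empty(subject.n_obs)
    for j, t in enumerate(subject.obs_times):
        before = starts[starts <= t + 1e-9]
        tald[j] = t - before.max() if before.size else t
    return tald


def pc_vpc(dataset: ObservationDataset, model: PopulationModel, n_sim: int = 500,
           bins: int | np.ndarray = 6, seed: int = 0) -> VpcResult:
    """Prediction-corrected visual predictive check on time after last dose."""
    if n_sim < 2:
        raise ValueError("n_sim must be at least 2 to form prediction bands")
    rng = np.random.default_rng(seed)
    pop_pred, tald, obs = [], [], []
    for subject in dataset.subjects:
        pop_pred.append(_pred_at_etas(subject, model, np.zeros(3)))
        tald.append(_time_after_last_dose(subject))
        obs.append(subject.obs_conc.astype(float))
    pop_pred = np.concatenate(pop_pred)
    tald = np.concatenate(tald)
    obs = np.concatenate(obs)

    if np.isscalar(bins):
        qs = np.linspace(0, 100, int(bins) + 1)
        edges = np.unique(np.percentile(tald, qs))
        if edges.size < 2:  # all observations at one time after last dose
            edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    else:
        edges = np.asarray(bins, dtype=float)
    idx = np.clip(np.searchsorted(edges, tald, side="right") - 1, 0,
                  len(edges) - 2)
    # merge empty bins with their left neighbor
    counts = np.bincount(idx, minlength=len(edges) - 1)
    if np.any(counts == 0):
        warnings.warn("empty VPC bin merged with neighbor")
        keep = np.concatenate([[True], counts[1:] > 0])
        edges = np.concatenate([edges[:-1][keep], edges[-1:]])
        idx = np.clip(np.searchsorted(edges, tald, side="right") - 1, 0,
                      len(edges) - 2)
    n_bins = len(edges) - 1

    bin_median_pred = np.array([np.median(pop_pred[idx == b]) for b in range(n_bins)])
    correction = bin_median_pred[idx] / pop_pred
    pc_obs = obs * correction

    sim_pct = np.empty((n_sim, n_bins, 3))
    for m in range(n_sim):
        sim_vals = []
        for subject in dataset.subjects:
            sims = _simulate_replicates(subject, model, 1, rng)[0]
            sim_vals.append(sims)
        pc_sim = np.concatenate(sim_vals) * correction
        for b in range(n_bins):
            sim_pct[m, b] = np.percentile(pc_sim[idx == b], [5, 50, 95])

    rows = []
    for b in range(n_bins):
        sel = idx == b
        o5, o50, o95 = np.percentile(pc_obs[sel], [5, 50, 95])
        row = {"t_lo": edges[b], "t_hi": edges[b + 1], "n": int(sel.sum()),
               "obs_p5": o5, "obs_p50": o50, "obs_p95": o95}
        for qi, q in enumerate((5, 50, 95)):
            lo, hi = np.percentile(sim_pct[:, b, qi], [5, 95])
            row[f"sim_p{q}_lo"], row[f"sim_p{q}_hi"] = lo, hi
            row[f"sim_p{q}"] = np.median(sim_pct[:, b, qi])
        rows.append(row)
    return VpcResult(pd.DataFrame(rows), n_sim)


def gof_tables(fit: FitResult, dataset: ObservationDataset,
               k_sim: int = 500, seed: int = 0,
               with_npde: bool = False) -> pd.DataFrame:
    """Tidy observed vs population/individual predictions (+residuals) table."""
    model = fit.estimates
    rows = []
    for subject in dataset.subjects:
        pop = _pred_at_etas(subject, model, np.zeros(3))
        mp = map_individual(model, subject, seed=seed)
        ipred = mp.predictions
        sd = model.error.sd(ipred)
        for j in range(subject.n_obs):
            rows.append({
                "subject_id": subject.subject_id,
                "time": subject.obs_times[j],
                "observed": subject.obs_conc[j],
                "population_pred": pop[j],
                "individual_pred": ipred[j],
                "iwres": (subject.obs_conc[j] - ipred[j]) / sd[j] if sd[j] > 0
                else np.nan,
            })
    table = pd.DataFrame(rows)
    if with_npde:
        nres = npde(dataset, model, k_sim=k_sim, seed=seed)
        table = table.merge(nres.table[["subject_id", "time", "npde"]],
                            on=["subject_id", "time"], how="left")
    return table
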