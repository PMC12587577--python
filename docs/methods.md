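# Methods

This note documents the models, algorithms and numerical choices behind
`cefadial`, and what its synthetic-data experiments do and do not show.

## Structural model and event handling

Total plasma cefazolin follows a linear one-compartment model with
zero-order intravenous infusions. Elimination is the sum of a residual
clearance CL (non-renal plus residual renal; acting always) and a
dialysis-machine clearance CLdial that acts only while a hemodialysis
session is running. Between any two event boundaries — infusion starts and
ends, session starts and ends — both the total input rate R and the
elimination constant k = CLtot/V are constant, so the concentration relaxes
exponentially toward R/(kV). The engine enumerates these breakpoints,
propagates the closed form across each segment (an `expm1` formulation
keeps small kΔ stable) and is exact to machine precision; a property suite
checks it against adaptive-step numerical integration at 1e−6 relative
tolerance, and mass balance (dose in = CL·AUC + CLdial·AUC_dialysis +
amount remaining) at 1e−8.

Exposure summaries are closed-form as well: on each segment the
concentration is monotone, so extrema lie at segment endpoints, AUC has an
analytic primitive, and band-crossing times come from inverting the
exponential — no grid search. A two-compartment extension integrates each
segment with an augmented matrix exponential (exact even when the
intercompartmental clearance is zero); it exists because both structures
were candidates during model development, but the one-compartment model is
the default everywhere.

Units are hours, mg, L and mg/L; time 0 is a subject's first event.
Dialysis sessions default to 4 h — session length is configurable
per-session because real prescriptions vary and the source protocol does
not pin it.

## Covariate model

Typical values are standardized to a 70-kg body weight and a 1-m² membrane:

- Vd scales linearly with BW (fixed exponent 1), CL with BW^0.75 (fixed
  allometric exponent);
- CLdial scales with membrane surface area, DMSA^1.26 (estimated exponent);
- DMSA falls back to 0.85·BSA(BW) when unrecorded (the center of the
  recommended 75–100% of body surface area), with
  BSA = (4·BW+7)/(BW+90); precedence is per-session DMSA, then
  subject-level DMSA, then the BSA fraction;
- fat-free mass uses the sex-specific maximum-FFM formula
  (WHSmax·HT²·BW/(WHS50·HT²+BW), constants 42.92/30.93 kg/m² male and
  37.99/35.98 female, heights in meters).

Generic power and categorical effects can be attached to any parameter, so
the covariate-selection workflow (forward step on BIC plus
between-subject-variability reduction) is not hard-wired to the final
model. Albumin is carried as a covariate and can be attached as a power
effect; the specific protein-binding regression forms examined during
model development are not reproduced.

## Statistical model

Between-subject variability is log-normal with a diagonal Ω — only
ω_CL = 1.07 and ω_Vd = 0.197 are reported in the final model, with the
CLdial variability explained away by the membrane area (ω_dial = 0).
Residual error is proportional (b = 0.398); additive and combined forms are
implemented for model development. Negative simulated concentrations from
the proportional error are kept in likelihoods and truncated at zero only
in reported datasets. Inter-occasion variability and correlated random
effects are out of scope.

## SAEM

`fit_saem` estimates typical values (on the log scale, enforcing
positivity), covariate coefficients flagged as estimated, omegas and the
residual-error magnitude:

- **E-step**: per subject, three Metropolis–Hastings kernels per iteration
  on η — an independence proposal from the prior, a joint random walk and
  componentwise random walks — with Robbins–Monro scale adaptation toward
  0.3/0.4 acceptance during exploration. Likelihoods reuse a precompiled
  per-subject segment plan, so a full 100-subject fit runs in seconds.
- **SA step**: sufficient statistics are accumulated with step 1 for the
  exploration iterations and 1/(k−k₀) during smoothing. During exploration
  the variance estimates are floored at 95% of their previous value per
  iteration (simulated annealing), which prevents early collapse.
- **M-step**: because individual log-parameters are linear in the
  intercepts and covariate coefficients given η, the update is a per-
  parameter least-squares solve; ω² and the proportional/additive error
  variance have closed forms. The combined error uses the SA-averaged
  weighted residual as a joint rescale — an approximation documented here
  because the final model's proportional error has an exact update.

A parameter whose coefficients are estimated needs a positive ω for the
regression M-step, so ω_dial is given a small starting value and floored at
0.02; on data generated with ω_dial = 0 it shrinks to ≈0.1, absorbing
Monte-Carlo noise without biasing the CLdial typical value or exponent
materially. Defaults are 300 exploration + 200 smoothing iterations and 5
chains below 30 subjects (1 otherwise).

Standard errors come from an empirical Fisher information: by the Fisher
identity the marginal score of a subject is the posterior expectation of
the complete-data score, estimated from post-convergence MH draws; the
information is the sum of outer products of these per-subject mean scores.
This is cheaper than a Louis estimator or bootstrap and adequate for
flagging ill-informed parameters; it is not exact in small samples.

The marginal log-likelihood uses per-subject importance sampling with a
multivariate-t (df 4) proposal centered at the MAP η with a
finite-difference Hessian scale; BIC penalizes subject-level parameters
with log(N_subjects) and residual-error parameters with
log(N_observations), a mixed-level convention that is configurable since
the reference software's bookkeeping is not public. A covariate effect is
retained when it lowers BIC *and* the affected parameter's ω.

## MAP-Bayes individualization

`map_individual` minimizes the classical MAP objective
½Σ((y−f(η))/sd)² + ½ηᵀdiag(ω²)⁻¹η by L-BFGS-B with prior restarts. The
residual standard deviations are iteratively reweighted: evaluated at the
previous sweep's predictions (floored at 0.5 mg/L, the assay's lower
calibration bound) and held fixed within each sweep, i.e. no log-variance
term. This choice makes noise-free rich data recover their generating η
exactly and keeps a single observation at the typical prediction from
moving the posterior mode — the behavior a dose-individualization tool
should have — at the cost of differing from the full heteroscedastic
likelihood used in SAEM by O(b²) terms.

## Diagnostics

NPDE follows the standard construction: k_sim replicate observation vectors
per subject (BSV + residual error), decorrelation of observed and simulated
vectors by the inverse Cholesky factor of the empirical simulation
covariance (ridge-regularized if singular), rank → probability (clamped to
[1/(2k), 1−1/(2k)]) → standard-normal quantile. The summary tests are a
one-sample t (mean 0), a chi-square on (n−1)s² (variance 1) and
Shapiro–Wilk (normality) — the reference analysis names the targets, not
the tests.

The prediction-corrected VPC bins on time after last dose (default six
equal-count bins, empty bins merged leftward), scales each observed and
simulated value by bin-median population prediction over own population
prediction, and compares observed 5/50/95th percentiles (linear
interpolation of order statistics) with 90% bands from replicate
simulations. With only six subjects the observed percentiles across bins
are strongly correlated through the shared η draws, so per-dataset band
coverage is noisy (≈0.8 on average across generator seeds, occasionally
much lower for an extreme-η realization); this is a property of small-n
VPCs, not a miscalibration of the bands.

## Dosing-regimen optimization

Target bands come from the free-trough rule: lo = (4/0.2)·MIC = 20·MIC,
hi = 80 mg/L; MIC 4 mg/L already collides with the cap and raises an
error. Regimens are weekly cycles: base infusions (30 min) at multiples of
6, 8, 12, 24 or 48 h from the cycle start plus an optional supplemental
dose at the end of each dialysis session; sessions run 09:00–13:00 on days
3, 5 and 8 of the published weekly depiction (equivalently days 1/3/5 of
the steady-state week). None of these clock times are stated in the source
protocol; they are package defaults, configurable on `RegimenSpec`.
Four weekly cycles are simulated and the last assessed.

The search objective is the expected fraction of the assessment week
inside the band for the population actually found in a residual-clearance
stratum:

- body weights on the 10–51 kg grid are weighted by the probability that a
  child of that weight has an individual CL inside the stratum (under the
  log-normal BSV, a high-CL stratum is populated almost exclusively by
  heavier children);
- within the stratum, CL follows its conditional (truncated log-normal)
  distribution, represented by five equally weighted quantiles;
- Vd variability enters through three-point Gauss–Hermite quadrature;
- the proportional residual error is folded in analytically: the
  instantaneous probability that a noisy concentration lies in the band is
  a closed form in the noise-free concentration, tabulated once and looked
  up.

Because doses are in mg/kg and the model is linear, every candidate's
profile is a linear combination of two unit-dose profiles per (interval,
body weight, CL/Vd node); the search sweeps a coarse 1-mg/kg grid over
base and post-dialysis doses and all intervals, then refines at 0.1 mg/kg,
evaluating attainment on a 0.5-h grid. Selection is lexicographic: maximize
attainment; among candidates within 0.1% of the best, minimize the weekly
dose; break remaining ties by fewer administrations. A noise-free
typical-subject variant (`include_variability=False`) is kept for
degenerate checks and for comparison: it selects cheaper regimens at low CL
and substantially more expensive ones at mid-to-high CL, because without
the error term the optimizer pins troughs at the band floor instead of
centering profiles. The population variant is the default because the
underlying attainment analysis is defined with structural parameters, BSV
and residual variability included.

`pta` reports the complementary Monte Carlo view: simulated subjects with
full BSV (optionally CL restricted to a stratum), attainment as the
fraction of the steady-state week in band, with residual error applied at
hourly checkpoints when requested (continuous-time observation noise would
make full-week attainment a measure-zero event, so a checkpoint convention
is required).

The stratified table reproduces the monotone dose sequence across the six
published CL ranges and flags strata where the whole week cannot be held in
band (the 40–80 mg/L band at high CL, in particular). Under the default
objective the selected daily doses are, from lowest to highest stratum,
approximately 3.5, 5.3, 9.4, 14.2, 18.6 and 22.6 mg/kg/day with dialysis
on days 3/5/8 — one shared mg/kg regimen per stratum across 10–51 kg.

## Synthetic data

The generator emulates the study design: the six-patient covariate fixture
(body weights 11.4–51 kg, membrane areas 0.2–1.55 m², session counts with
median 8 and range 1–13) or sampled populations (BW ~ Uniform(10, 70) kg,
DMSA = 0.85·BSA); 20 mg/kg infusions of 30 min every 24 h by default
(the study's per-infusion doses ranged 4.9–26.3 mg/kg across 6–48 h
intervals); three 4-h sessions per week; TDM-style sampling at
end-of-infusion peaks, pre-dose troughs and pre-/intra-/post-dialysis
draws. The recovery design uses a fixed 12-point schedule including two
intra-dialysis and one post-dialysis sample, which is what identifies
CLdial. Every generated study carries its ground truth (etas, individual
parameters, noise-free predictions) for recovery tests, and outlier
injection (multiply/divide by a factor) supports residual-flagging
exercises.

What passing tests show — and what they do not: parameter recovery,
diagnostic calibration and dosing results are demonstrated on data whose
generating process *is* the model. Real pediatric dialysis data add
within-subject variability over weeks of treatment, dose-adaptation
feedback (doses were adjusted on measured concentrations), assay error
structure beyond proportional Gaussian, and covariate measurement error —
none of which the generator emulates. The recovery experiments therefore
validate the estimation machinery, not the clinical model itself.

## Problem sizes and reproducibility

Default experiment sizes were chosen so each analysis is statistically
informative while remaining quick: the recovery experiment uses 100
subjects × 12 samples (sampling noise on the typical-CL estimate is then
ω_CL/√100 ≈ 11%, the dominant uncertainty); NPDE/VPC use 300–500
simulation replicates, matching the reference analysis's 500; the dosing
search evaluates ≈10⁴ candidate regimens per stratum through the
superposition trick. All stochastic entry points take explicit seeds and
are bit-reproducible given one; `scripts/acceptance.py` derives all of its
seeds from a single `--seed`.

## Known limitations

- Ω is diagonal; no inter-occasion variability; no BLQ likelihood (the
  study had no BLQ samples — BLQ rows are excluded with a count).
- The empirical-Fisher standard errors understate uncertainty for
  parameters whose information comes through few subjects.
- The combined-error M-step is approximate (documented above).
- Dialysis clock times, session lengths and the candidate-regimen grid are
  package conventions; published daily doses are reproduced to within
  about ±20% for five of the six strata, with the lowest stratum selected
  ≈25% cheaper than the published figure under this package's
  attainment-first objective.
- Free (unbound) concentrations are never modeled; all targets are total
  concentrations with the 20% free fraction folded into the band bounds.
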