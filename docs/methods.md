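# Methods

## Setting and model

Two-arm longitudinal trial, outcome measured at visits `j = 1..J`
(baseline is visit 0 and enters only as a covariate), arm `T ∈ {0 =
reference, 1 = active}`.  Patient `i` withdraws from treatment after visit
`D_i` (`D = J` for on-treatment completers) and leaves the study after
visit `S_i ≥ D_i`; outcomes at `D < j ≤ S` are observed off treatment,
outcomes after `S` are missing.  Missingness after `S` is monotone by
construction; intermediate missing values before `S` are accepted and
treated as MAR by the sampler.

The imputation model is a repeated-measures multivariate normal,
`Y_i ~ MVN(X_i β + offset_i, Σ)` with unstructured `Σ` (optionally one per
arm).  The mean has three blocks:

* **Core block** — every cell's reference-based mean written as a linear
  functional of the on-treatment means `μ_tj` (plus a fixed offset where
  needed).  On treatment the functional is `μ_tj` for every core.  Off
  treatment: J2R → `μ_0j`; CIR → `μ_0j + μ_tk − μ_0k`; LMCF → `μ_tk`;
  MAR → `μ_tj`; MAR+delta → `μ_tj + δ_t(j−k)` (offset); RTB → baseline
  mean (offset; pooled across arms by default, per-arm optional).  CR is
  applied to off-treatment cells only, where it coincides with J2R in
  this framework; it is included for completeness and documented as such.
* **Deviation block** — compliance-model departures from the core:
  `γ*_tkj` indexed by (arm, deviation visit, visit) for the *historic*
  model (`2·J(J−1)/2` columns), `α*_tj` for the *current* model (`2(J−1)`
  columns).  Rows are zero at all on-treatment cells.  A *full-pattern*
  variant (subject-level pattern × every visit) is available behind a
  flag; by its definition its columns are active at on-treatment cells of
  deviators too, and no nesting guarantee beyond the rank report applies.
* **Baseline block** — baseline × visit × treatment by default
  (`baseline="visit_trt"`); a flag drops the treatment interaction or the
  block entirely.

Deviation columns for cells that never occur in the observed data are
**kept**.  Their marginal posterior is exactly their prior (missing cells
contribute no information once integrated out), which is precisely the
mechanism that makes perforated datasets analysable; the design reports
them (`never_observed`).

### Nesting

The core must be nested in the compliance model: its implied off-treatment
mean must be constant across the cells pooled into one compliance stratum,
otherwise the compliance fit is distorted.  `check_nesting` tests this
numerically: each off-treatment cell's core mean is expressed as a vector
over (μ weights, constant); within every compliance stratum the vectors
must agree to a relative tolerance of 1e−8.  This reproduces the expected
compatibility matrix — history-free cores (J2R/CR, MAR, RTB, constant
delta) pass with both current and historic; history-dependent cores (CIR,
LMCF, ramped delta) pass only with historic — and lists offending cells.

## Priors

* Core coefficients: zero-mean normal with variance `diffuse_scale ×
  var(observed outcomes)`, `diffuse_scale = 1e6` — effectively flat yet
  proper, keeping every full conditional conjugate.
* Deviation coefficients: zero-centred normal with variance `v` (outcome
  units squared).  Default `v` is the `(J, J)` residual variance of a
  repeated-measures ML fit to on-treatment data only (`mmrm_residual`),
  i.e. roughly one extra patient-visit of likelihood behind the core; a
  range-based alternative `((max − min)/6)²` of the observed final-visit
  outcomes is provided.  An optional correlation `adjacent_corr·v`
  (default 0) links visit-adjacent deviations within the same (t, k)
  group; positive definiteness is verified by Cholesky.
* Covariance: inverse-Wishart with `df = J + 2` (the weakest proper
  conjugate choice) and scale `I × var(observed outcomes)`; configurable,
  and grouped by arm on request (default off — a single covariance).

The classic-RBI limit `v → 0` is implemented by *structurally dropping*
the deviation columns (`pin_deviation=True`) rather than by a tiny
variance, avoiding conditioning problems and making the limit exact.

## Sampler

Pure conjugate Gibbs, all draws direct:

1. missing cells per patient from the conditional MVN given observed
   cells and current (β, Σ), vectorised over missingness patterns;
2. β from its Gaussian full conditional (Cholesky solve of the posterior
   precision; per-visit Gram tensors are precomputed once);
3. Σ from its inverse-Wishart full conditional (jitter-and-retry on a
   numerically non-PD scale, failing after 5 attempts).

Initialisation: β from the on-treatment repeated-measures ML fit with
deviations at zero, Σ from the same fit, missing cells at their
conditional means; a prior-based fallback is used if that fit fails.
Defaults `n_burn = 1000`, `thin = 1` (direct sampling leaves little serial
correlation; deviation coefficients behind large missing strata are the
exception — the perforated-data test thins by 10), `K = 200` imputations.
One root `numpy` Generator drives the whole chain; identical seeds give
bit-identical draws.  The Monte Carlo SE of the pooled estimate, √(B/K),
is reported so K can be chosen for the precision required (about 10⁴ for
two stable decimals).

The on-treatment repeated-measures fit (`mmrm_reference_fit`) is an EM
algorithm over the incomplete on-treatment vectors (off-treatment and
missing cells excluded from the likelihood), tolerance 1e−8, max 500
iterations.  No installed package fits this model with an unstructured
covariance, so it is implemented here.  Degenerate inputs error out:
arms with fewer than two patients, visits with no on-treatment data.

## Analysis and pooling

Each completed dataset preserves observed values bit-identically and is
analysed by ANCOVA of the final-visit outcome on treatment and baseline
(statsmodels OLS; the outcome is assumed to be change from baseline, with
a loader toggle to compute it from raw scores).  Rubin's rules give
`T = W̄ + (1 + 1/K)B`; degrees of freedom use the Barnard–Rubin
small-sample form against a complete-data df of `n − 3` (the ANCOVA's
residual df), chosen because trial sample sizes are modest.  Published
SEs computed under the older large-sample df rule may differ in the
second decimal.

Comparators: `run_classic_rbi` (deviations pinned; off-treatment data
optionally excluded from the likelihood and/or merged back over their
imputations) and `run_compliance_mi` (the uncentred compliance model with
diffuse priors — the `v → ∞` reference point).

## Exact bias/RMSE in the one-visit setting

Single outcome, known `σ²` (set to 1, matching how the calculator is
used; the Gibbs engine by contrast samples Σ), deviation probability
`p_t`, missingness `q_t` given deviation, means `μ_on,t`, `μ_off,t` with
`μ_miss,t = μ_off,t`, and the centred model `μ_off,t = μ_on,0 + γ_t`,
`γ_t ~ N(0, σ²/ρ)` with flat priors on the on-treatment means.  `ρ` is
the prior precision relative to the residual precision — the number of
core-model pseudo-observations.

At infinite imputations the MI point estimate replaces each missing group
by the posterior mean of `μ_on,0 + γ_t`.  The posterior of
`(μ_on,0, γ_0, γ_1)` is jointly Gaussian with a 3×3 precision determined
by the counts (a = reference on, b/c = off-observed per arm), so the
estimate is linear in the observed group means, and its conditional
moments are closed-form.  Two conventions are implemented for the
imputation target: the **joint** posterior mean (default — it is what the
full Bayesian sampler does; observed off-treatment data feed back into
the reference anchor) and the **plug-in** form `μ̂ = ȳ_on,0`,
`γ̂_t = b(ȳ_off,t − ȳ_on,0)/(b + ρ)`.  They differ only at order 1/n: with
identical rates and γ in both arms the plug-in bias is exactly zero by
symmetry while the joint form retains a feedback term below 5×10⁻⁴ at
n = 100 — invisible at plotting resolution but measurable.

Definitions: the *conditional bias* is taken against the
conditional-on-counts treatment-policy mean (so it is identically zero
when no imputation occurs, and its pmf-weighted sum is the marginal bias
against the population contrast TE); the *conditional MSE* is against TE
so its weighted sum is the marginal squared error.  The marginal
summation runs over `n_dev,t ~ Bin(n, p_t)`, `n_miss,t | n_dev,t ~
Bin(n_dev,t, q_t)` independently per arm, truncated to patterns with pmf
above 1e−14 and renormalised (retained mass ≥ 1 − 1e−10, far below every
tolerance in use); the posterior weights are computed once per distinct
(a, b, c) triple.  Degenerate patterns with a singular 3-parameter system
(essentially zero probability at the design points used) fall back to a
zero-weight imputation; at `ρ = 0` an arm with no observed off-treatment
data has a genuinely flat posterior for its γ and the code substitutes
the reference anchor (the jump-to-reference fallback).

`mc_oracle` simulates whole trials (counts, then group means) and applies
the same estimator; it cross-checks the moment integration, not the
estimator definition.  The arm-swap symmetry (swapping arms negates the
bias) holds exactly when deviation and missingness rates are common to
the two arms; with unequal rates the reference anchoring breaks it, which
is the point of the asymmetric-deviation scenario.

## Synthetic generator

Emulates the structure of the motivating antidepressant example: J = 4
post-baseline visits, 88/84 patients, visit-wise deviation hazards
calibrated to the published on-treatment counts, all-or-nothing follow-up
(each deviator stops immediately with probability q or is observed to the
end), baseline ~ N(18, 5²) entering each visit with coefficient −0.2
(centred, so the configured μ remain the marginal means), declining mean
profiles (reference ≈ −1/visit, active ≈ −2/visit) and an unstructured
covariance with final-visit variance 40 and correlation 0.6^|j−j'| —
chosen so the published default prior variance (40) is the natural one on
this scale.  Off-treatment means follow a configurable truth (J2R, CIR,
MAR, or a custom γ table).  Deviation is outcome-independent by default
(the analytic module assumes it); a DNAR coefficient shifts the hazard
with the current standardised residual for stress tests, outside the
method's guarantee.  `example_layout_trial` fixes the exact published
(arm × deviation-visit × stop/continue) frequencies of the covered and
perforated layouts — a synthetic stand-in reproducing the pattern
bookkeeping only, not the outcome values.  Perforation forces chosen
strata to stop at deviation and errors if a requested stratum is empty.

What passing tests show, and what they do not: the generator draws
genuinely multivariate-normal trajectories with a correctly specified
mean under each truth rule, so parameter-recovery and coverage results
demonstrate internal consistency of the sampler, pooling and calculator —
not robustness to model misspecification (non-normal outcomes,
outcome-dependent withdrawal, irregular visit times, site effects), which
real trials will feature.

## Problem sizes and numerical choices in the tests

Unit and property tests run at desk scale (J = 3, 30–120 patients/arm);
the coverage check uses 200 replicates of a 40/arm CIR-truth trial with
K = 30 imputations; the analytic-vs-oracle comparison uses 10⁶ simulated
trials per scenario/ρ; the perforated-posterior check stores 1200 draws
thinned by 10 so the sample variance of a prior-only coefficient is
estimated to a few percent.  Tolerances follow the quantity being
checked: exact arithmetic to 1e−10–1e−12, Monte Carlo comparisons to 3–5
standard errors, moment recovery to 3–4 sampling SEs.

## Known limitations

* Gaussian outcomes only; no recurrent-event, binary or time-to-event
  extensions, and no covariance switching at deviation.
* Missing baseline is an error; the model conditions on baseline
  throughout.
* The current-model deviation `α*_t2`-type parameters matter only when
  patients with partial off-treatment follow-up need imputation at
  intermediate visits; the example layouts never exercise this path,
  though the loader and sampler support it.
* Rubin's variance for reference-based imputation is known to be
  conservative relative to the repeated-sampling variance; coverage above
  the nominal level is expected and observed.
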