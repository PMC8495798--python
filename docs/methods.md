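# Methods

## Model

Each plot × species presence series is modeled by a three-state hidden
Markov chain over `Z_t = (S_{t−1}, X_t)`, where `S_t` indicates viable
seeds in the soil and `X_t` the standing flora seen in the annual spring
survey. Seeds are the only persistence mechanism: a species seen at `t`
certainly sets seed (state 3 cannot move to the empty state, hence the
structural zero in the transition matrix), an unseen species may persist
as dormant seed (state 2), and an empty plot can only be refounded by
outside colonization. The four probabilities — germination `g`, seed
survival `s`, colonization `c` and the initial condition `p0` — are
assumed constant over the study years for a given plot × species.

Emission is deterministic, i.e. the model has no false-presence or
false-absence observation error; what it *does* absorb is unsurveyed
plot-years, which enter the forward recursion as an emission row of ones
so the hidden chain still advances one calendar year. Missing surveys are
never imputed or dropped.

### First year

`Z_1 = (S_0, X_1)` already couples the pre-study seed bank to the first
observation: the initial vector `(1−p0, p0(1−g), p0·g)` is the
distribution of `Z_1`, and the first observation acts on it as a
consistency filter. This is the only reading under which `p0` is "seeds
in the soil the year before the first survey".

### Multilevel layer

One focal parameter θ ∈ {g, s, c} per fit carries the full structure

    logit θ_ij = Σ_k α_kj x_ik ,   x_i = (1, latitude, pH, silt, clay,
                                          mowing, tillage, herbicide)_i

with species-level random coefficients whose means are constants
(environmental terms, k = 0..4) or linear in centered/scaled log₁₀ seed
mass (management terms, k = 5..7). Running one model per demographic
parameter keeps each fit identifiable with binary panel data of this
size; the two non-focal parameters get species-level logit-normal random
intercepts `logit θ_j ~ N(µ, τ²)` and `p0_j ~ Uniform(0, 1)` per species.
`ModelSpec(joint=True)` instead puts the full structure on all three
parameters in a single fit; it is slower and only weakly identified at
the default design size, and is off by default.

### Priors

The hyper-values are a modelling choice of this package: regression-level
locations (ᾱ_k, γ_k, β_k, µ) are N(0, 1.5²) — weakly informative on the
logit scale, keeping implied probabilities away from a point mass at 0/1 —
and all random-effect sd's (σ_k, τ) are Uniform(0, 5). Both are
configurable through `ModelSpec`.

## Computation

* **Likelihood.** Scaled forward recursion (per-step normalization with
  accumulated log normalizers), exact for any series length; a brute-force
  3^T path enumeration built from the same matrices serves as an
  independent oracle in the tests. A vectorized batch kernel evaluates all
  plot × species series at once and is numba-compiled when numba is
  importable (a pure-python/numpy kernel is the reference and fallback).
* **Clamping.** Inside the sampler, probabilities obtained from the
  inverse logit are clamped to [1e-12, 1−1e-12] so boundary proposals
  under logit-normal effects never produce log(0). The user-facing
  `forward_loglik` is exact and will return −inf for impossible series.
* **Sampler.** Blocked adaptive Metropolis-within-Gibbs on the
  marginalized posterior. Species blocks are conditionally independent
  given the hyperparameters, so each coefficient column α_k· is updated
  for all species in parallel with a single batched likelihood evaluation
  (one accept/reject per species); the same applies to the nuisance
  logits and to p0 (reflective random walk in (0,1)). Population means and
  the (γ_k, β_k) lines are conjugate normal draws; each σ² is an inverse
  gamma draw truncated at the uniform prior bound (flat prior on σ gives
  σ² | α ~ InvGamma((J−1)/2, SS/2)). Proposal scales adapt by
  Robbins–Monro toward 0.44 acceptance during burn-in only, so the
  post-burn-in chain is a valid fixed-kernel MCMC. A numerical floor of
  0.01 on sd draws guards the degenerate all-equal-coefficients state.
* **Initial values.** Chain 1 starts from prior means, subsequent chains
  from independent prior draws; chain seeds derive from the single run
  seed via `SeedSequence`, making every fit exactly reproducible.
* **Defaults.** 2 chains × 10,000 iterations with 2,500 burn-in. The
  recovery and calibration experiments in the test suite and the
  acceptance script use 2 × 3,000 (burn-in 1,000) and 2 × 2,000 (burn-in
  800) at 40 × 25 × 8 and 24 × 15 × 7 designs respectively — sizes chosen
  so a full replicate experiment is a desk-scale computation while leaving
  effective sample sizes in the hundreds and split-rhat ≈ 1.01 for the
  hyperparameters.

## Reporting

Summaries are posterior means with equal-tailed 95% credible intervals
(the BUGS-era convention, not HPD), split-chain rhat and bulk effective
sample size via ArviZ; constant (point-mass) chains report rhat = 1. An
effect is significant when its interval excludes zero, with zero on an
endpoint counting as *not* excluded (conservative tie-break). The
explained variance of the seed-mass regression is the multilevel
decomposition

    R²_k = 1 − E[ V_j(α_kj − γ_k − β_k·trait_j) ] / E[ V_j(α_kj) ]

(expectations over posterior draws, V_j the finite-sample variance across
species, clipped to [0, 1]); for degenerate draws it reduces to classical
regression R². The citation trail for the original explained-variance
formula is ambiguous, so this definition is the package's own documented
choice.

## Synthetic data

The generator emulates a multi-region vineyard flora survey and is the
exact generative counterpart of the fitted model: 46 plots, 30 species,
7 annual surveys, 10% of plot-years unsurveyed at the survey level (the
same plot-years missing for every species), latitude uniform on
43.4–49.3°, pH N(7.0, 0.7²), soil texture from a Dirichlet over
(sand, silt, clay) so fractions are feasible by construction, management
intensities as yearly Poisson counts (means 2, 2, 1.5) averaged over the
study years, and seed masses log-uniform on 0.1–14.5 mg. Species
coefficients are drawn from the random-effect distributions, series from
the hidden chain, and the full latent truth (coefficients, hidden states)
is returned for recovery experiments.

What it does **not** emulate: spatial autocorrelation between plots,
temporal variation in management within a plot, row vs inter-row
sub-plot structure, phylogenetic correlation among species effects, and
detection error. Passing recovery tests therefore show the estimator is
correct *under the model's own assumptions*; they do not certify those
assumptions for any real survey.

## Design choices and conventions

* Management covariates are aggregated to per-plot mean annual counts,
  matching the single-index regression; `aggregate_management_years`
  collapses year-wise records and offers per-plot totals instead
  (`how="total"`).
* Covariates are standardized with the population-sd convention; the
  original (mean, sd) pairs are retained for back-transformation.
  Constant covariates are zeroed and flagged rather than dropped.
* Silt/clay are accepted as percent or proportion (auto-detected at read
  time: values > 1 mean percent).
* Seed mass is handled in mg; it enters the model as log₁₀ mass centered
  and scaled across the modeled species.

## Limitations

Demographic parameters are confounded along known ridges of this model
family (e.g. high `s` with low `c` can mimic low `s` with high `c` for
short series), so per-species point estimates at 7–8 years carry wide
intervals; the hierarchical structure is what makes the population-level
slopes well estimated. Series shorter than ~4 observed years contribute
little information about `s`. The sampler is a random-walk scheme: for
much larger designs (hundreds of plots, long series) a gradient-based
sampler over the same marginalized likelihood would mix faster.
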