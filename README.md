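# seedbankhmm

Multilevel hidden Markov models for weed seed-bank demography estimated
from yearly above-ground presence–absence surveys.

## The problem

Arable weeds persist in fields through a soil seed bank that no routine
survey observes. Annual flora surveys only record whether a species'
standing plants were seen in a plot each spring. `seedbankhmm` treats the
seed bank as the hidden state of a Markov chain and estimates, for every
plot × species, the demographic probabilities that drive local dynamics:

* **g** — germination and survival to adulthood within a year,
* **s** — one-year seed-bank survival without new seed input,
* **c** — external colonization (arrival and survival of outside seed),
* **p0** — seeds present the year before the first survey.

It is written for plant ecologists and agronomists analysing multi-year
binary occupancy panels (the motivating design: 46 vineyard plots, 30
species, 7 annual surveys, some plot-years unsurveyed) who want to relate
those rates to environment, management intensity and species traits.

## The model

The hidden chain is `Z_t = (S_{t−1}, X_t)` with `S_t` the seed-bank
indicator and `X_t` the observed presence: state 1 = (0,0), 2 = (1,0),
3 = (1,1). Emission is deterministic (only state 3 is "present"). The
initial vector is `(1−p0, p0(1−g), p0·g)` and the transition matrix

```
        (0,0)              (1,0)                  (1,1)
(0,0)   1−c                c(1−g)                 c·g
(1,0)   (1−c)(1−s)         [1−(1−c)(1−s)](1−g)    [1−(1−c)(1−s)]·g
(1,1)   0                  1−g                    g
```

The forward algorithm gives the exact likelihood of each series, with
unsurveyed years marginalized. On top, a multilevel regression lets one
focal parameter θ ∈ {g, s, c} vary with plot covariates and species:

```
logit θ_ij = α_0j + α_1j·latitude_i + α_2j·pH_i + α_3j·silt_i + α_4j·clay_i
           + α_5j·mowing_i + α_6j·tillage_i + α_7j·herbicide_i

α_kj ~ N(ᾱ_k, σ_k²)                      k = 0..4
α_kj ~ N(γ_k + β_k·seedmass_j, σ_k²)     k = 5, 6, 7
```

with `seedmass_j` the centered/scaled log₁₀ seed mass, so `β_k` measures
how a species' response to management practice *k* changes with seed
size. Fitting is Bayesian MCMC (adaptive Metropolis-within-Gibbs on the
marginalized likelihood; hidden states are never sampled), two chains
with overdispersed starts, and an effect is declared significant when its
95% equal-tailed credible interval excludes zero.

## Worked example

`python examples/03_fit_and_report.py` simulates a 40-plot × 25-species
× 8-year survey whose true seed-mass slopes are 0.4 / 0.6 / 0.8 for
mowing / tillage / herbicide, fits the germination model (2 chains ×
3,000 iterations) and prints:

```
seed-mass slopes per management practice:
  mowing     beta = +0.456 [+0.307, +0.604] (truth +0.40, significant: True, R2 = 0.77)
  tillage    beta = +0.668 [+0.509, +0.838] (truth +0.60, significant: True, R2 = 0.85)
  herbicide  beta = +0.749 [+0.606, +0.898] (truth +0.80, significant: True, R2 = 0.92)
```

Each line is the posterior mean and 95% credible interval of `β_k`: all
three intervals cover the truth and exclude zero, and R² is the share of
between-species slope variance explained by log seed mass. The same
script prints the per-covariate effect table and the per-species
posterior-mean demographic rates.

The other examples show the forward likelihood against brute-force path
enumeration (`01_forward_likelihood.py`) and the structure of the
synthetic survey generator (`02_simulate_survey.py`). A thin CLI wraps
the same calls: `seedbankhmm simulate|fit|summarize|recover --config
config.yaml --seed N --out-dir D`.

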