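"""Posterior summaries, convergence diagnostics, the interval significance
rule, multilevel explained variance and the slope-vs-seed-mass tables.

Credible intervals are equal-tailed. An effect is declared significant when
its 95% interval excludes zero; zero exactly on an endpoint counts as not
excluded. Explained variance for the species-coefficient regression uses
the multilevel decomposition

    R2_k = 1 - E[ V_j( a_kj - (gamma_k + beta_k * trait_j) ) ] / E[ V_j(a_kj) ]

with V_j the finite-sample variance across species and the expectation
taken over posterior draws; for degenerate (point-mass) draws it reduces to
the classical regression R2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .hierarchy import PosteriorDraws
from .io import COVARIATE_NAMES, MANAGEMENT_NAMES

__all__ = [
    "summarize",
    "summarize_array",
    "significance",
    "explained_variance",
    "effect_table",
    "slope_trait_table",
    "species_demography_table",
    "SlopeTraitFit",
    "convergence_flags",
]

RHAT_THRESHOLD = 1.1


def summarize_array(draws: np.ndarray, name: str = "x") -> pd.DataFrame:
    """Summary table for one quantity's draws of shape (chains, iters, ...).

    One row per scalar element: posterior mean, equal-tailed 95% interval,
    split-chain rhat and bulk effective sample size.  With a single chain
    rhat is reported as NaN.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim < 2:
        raise ValueError("draws must have shape (chains, iterations, ...)")
    chains, iters = draws.shape[:2]
    flat = draws.reshape(chains, iters, -1)
    k = flat.shape[2]
    labels = (
        [name]
        if draws.ndim == 2
        else [
            f"{name}[{','.join(map(str, np.unravel_index(m, draws.shape[2:])))}]"
            for m in range(k)
        ]
    )
    rows = []
    for m in range(k):
        x = flat[:, :, m]
        if np.ptp(x) == 0.0:  # degenerate point mass: trivially converged
            rhat, ess = (1.0 if chains >= 2 else np.nan), float(x.size)
        else:
            data = az.convert_to_dataset(x)
            ess = float(az.ess(data)["x"].values)
            rhat = float(az.rhat(data)["x"].values) if chains >= 2 else np.nan
        if chains < 2 and m == 0:
            warnings.warn("single chain: rhat cannot be computed", stacklevel=2)
        lo, hi = np.quantile(x, [0.025, 0.975])
        rows.append(
            {
                "quantity": labels[m],
                "mean": float(x.mean()),
                "lower": float(lo),
                "upper": float(hi),
                "rhat": rhat,
                "ess": ess,
            }
        )
    return pd.DataFrame(rows)


def summarize(draws: PosteriorDraws, names: list[str] | None = None) -> pd.DataFrame:
    """Summary table over all (or the named) stored quantities, post burn-in."""
    names = list(draws.draws) if names is None else names
    parts = [summarize_array(draws.posterior(n), n) for n in names]
    return pd.concat(parts, ignore_index=True)


def significance(lower: float, upper: float) -> bool:
    """True iff the interval [lower, upper] strictly excludes zero."""
    if not lower <= upper:
        raise ValueError("need lower <= upper")
    return bool(lower > 0.0 or upper < 0.0)


def convergence_flags(summary: pd.DataFrame, threshold: float = RHAT_THRESHOLD) -> pd.DataFrame:
    """Rows of a summary whose rhat exceeds the threshold."""
    return summary[summary["rhat"] > threshold]


def explained_variance(
    alpha_draws: np.ndarray,
    gamma_draws: np.ndarray,
    beta_draws: np.ndarray,
    traits: np.ndarray,
) -> float:
    """Proportion of between-species coefficient variance explained by seed mass.

    Parameters
    ----------
    alpha_draws : (n_draws, n_species)
        Posterior draws of one management coefficient across species.
    gamma_draws, beta_draws : (n_draws,)
        Matching draws of the line intercept and seed-mass slope.
    traits : (n_species,)
        Centered/scaled log10 seed mass.
    """
    alpha_draws = np.asarray(alpha_draws, dtype=float)
    traits = np.asarray(traits, dtype=float)
    if traits.size < 3:
        raise ValueError("explained variance needs at least 3 species")
    line = np.asarray(gamma_draws)[:, None] + np.asarray(beta_draws)[:, None] * traits[None, :]
    resid_var = np.var(alpha_draws - line, axis=1, ddof=1).mean()
    total_var = np.var(alpha_draws, axis=1, ddof=1).mean()
    if total_var == 0.0:
        return 0.0
    return float(np.clip(1.0 - resid_var / total_var, 0.0, 1.0))


def effect_table(draws: PosteriorDraws, param: str | None = None) -> pd.DataFrame:
    """Plot-level environmental effect summaries (latitude, pH, silt, clay).

    The data behind the forest-plot panels: one row per covariate with the
    posterior mean, 95% interval and the interval significance rule.
    """
    param = param or draws.spec.focal
    abar = draws.posterior(f"{param}_alpha_bar")  # (chains, iters, 5)
    rows = []
    for k, cov_name in enumerate(COVARIATE_NAMES[:4], start=1):
        summ = summarize_array(abar[:, :, k], f"{param}_alpha_bar[{k}]").iloc[0]
        rows.append(
            {
                "parameter": param,
                "covariate": cov_name,
                "mean": summ["mean"],
                "lower": summ["lower"],
                "upper": summ["upper"],
                "rhat": summ["rhat"],
                "significant": significance(summ["lower"], summ["upper"]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SlopeTraitFit:
    """Per-practice species slopes against seed mass: one forest-plot panel."""

    parameter: str
    practice: str
    species: pd.DataFrame  # per-species slope mean, lower, upper, trait
    line: pd.DataFrame  # trait grid with fitted gamma + beta * trait
    gamma_mean: float
    beta_mean: float
    beta_lower: float
    beta_upper: float
    beta_significant: bool
    r_squared: float


def slope_trait_table(
    draws: PosteriorDraws, param: str | None = None, n_grid: int = 50
) -> dict[str, SlopeTraitFit]:
    """Slope-vs-seed-mass fits for mowing, tillage and herbicide.

    For each management practice: the per-species posterior-mean coefficient
    with its 95% interval, the fitted population line over the observed
    trait range, the trait-slope summary and the explained variance.
    """
    param = param or draws.spec.focal
    traits = np.asarray(draws.traits, dtype=float)
    alpha = draws.flat(f"{param}_alpha")  # (n, J, 8)
    gamma = draws.flat(f"{param}_gamma")  # (n, 3)
    beta = draws.flat(f"{param}_beta")
    grid = np.linspace(traits.min(), traits.max(), n_grid)
    out: dict[str, SlopeTraitFit] = {}
    for m, practice in enumerate(MANAGEMENT_NAMES):
        k = 5 + m
        a = alpha[:, :, k]  # (n, J)
        lo, hi = np.quantile(a, [0.025, 0.975], axis=0)
        species = pd.DataFrame(
            {
                "species_id": draws.species_ids,
                "trait": traits,
                "slope_mean": a.mean(axis=0),
                "lower": lo,
                "upper": hi,
            }
        )
        b_lo, b_hi = np.quantile(beta[:, m], [0.025, 0.975])
        gm, bm = float(gamma[:, m].mean()), float(beta[:, m].mean())
        line = pd.DataFrame({"trait": grid, "fitted": gm + bm * grid})
        out[practice] = SlopeTraitFit(
            parameter=param,
            practice=practice,
            species=species,
            line=line,
            gamma_mean=gm,
            beta_mean=bm,
            beta_lower=float(b_lo),
            beta_upper=float(b_hi),
            beta_significant=significance(float(b_lo), float(b_hi)),
            r_squared=explained_variance(a, gamma[:, m], beta[:, m], traits),
        )
    return out


def species_demography_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-species posterior means of g, s, c at covariate means, plus p0.

    The structured parameter is evaluated at the covariate means (all
    standardized covariates zero), i.e. via its species intercept; nuisance
    parameters through their species logit intercepts.
    """
    from scipy.special import expit

    spec = draws.spec
    rows = {"species_id": draws.species_ids}
    for p in spec.structured:
        rows[p] = expit(draws.flat(f"{p}_alpha")[:, :, 0]).mean(axis=0)
    for p in spec.nuisance:
        rows[p] = expit(draws.flat(f"{p}_eta")).mean(axis=0)
    rows["p0"] = draws.flat("p0").mean(axis=0)
    return pd.DataFrame(rows)[["species_id", *sorted(set(rows) - {"species_id"})]]
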