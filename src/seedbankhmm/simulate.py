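"""Synthetic survey data with the full statistical structure of the model.

Emulates a multi-region vineyard flora survey: ~46 plots followed over 7
annual spring surveys for 30 weed species, with plot-level environmental
and management covariates and species seed masses spanning 0.1-14.5 mg.
Species coefficients are drawn from the random-effect distributions, each
plot x species presence series is simulated from the three-state seed-bank
chain, and whole plot-years are masked as unsurveyed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .hierarchy import HyperParams, PARAM_NAMES
from .hmm import MISSING, build_initial, build_transition
from .io import (
    COVARIATE_NAMES,
    ModelDataset,
    PlotCovariates,
    SpeciesTraits,
    SurveyPanel,
    standardize_covariates,
)

__all__ = ["DesignSpec", "default_truth", "generate_covariates", "generate_traits",
           "generate_dataset", "dataset_to_tables"]


def default_truth() -> dict:
    """Generative truth used by the default design.

    The focal parameter (germination) carries the covariate + seed-mass
    structure; seed survival and colonization are species-level logit-normal
    intercepts, p0 is Uniform(0, 1) per species — mirroring the structure the
    fit assumes.
    """
    return {
        "focal": "g",
        "hyper": HyperParams(
            alpha_bar=np.array([0.0, 0.3, -0.3, 0.2, -0.2]),
            gamma=np.zeros(3),
            beta=np.array([0.4, 0.6, 0.8]),
            sigma=np.full(8, 0.3),
        ),
        # non-focal parameters: (mean, sd) of the species logit intercepts
        "nuisance": {"s": (0.0, 0.5), "c": (-0.85, 0.5)},
    }


@dataclass
class DesignSpec:
    """Survey design and generative truth for one synthetic dataset.

    Defaults mirror the vineyard study: 46 plots, 30 species, annual
    surveys 2006-2012, ~10% of plot-years unsurveyed, seed masses
    log-uniform over 0.1-14.5 mg.
    """

    n_plots: int = 46
    n_species: int = 30
    years: tuple[int, int] = (2006, 2012)
    missing_rate: float = 0.1
    seed_mass_range_mg: tuple[float, float] = (0.1, 14.5)
    latitude_range: tuple[float, float] = (43.4, 49.3)
    ph_mean_sd: tuple[float, float] = (7.0, 0.7)
    texture_dirichlet: tuple[float, float, float] = (4.0, 3.0, 3.0)  # sand, silt, clay
    management_means: tuple[float, float, float] = (2.0, 2.0, 1.5)  # mowing, tillage, herbicide
    truth: dict = field(default_factory=default_truth)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.n_species < 1:
            raise ValueError("need at least one plot and one species")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @classmethod
    def small(cls, **kw) -> "DesignSpec":
        """Fast preset for tests: 8 plots, 6 species, 6 years."""
        return cls(n_plots=8, n_species=6, years=(2006, 2011), **kw)


def generate_covariates(design: DesignSpec, rng: np.random.Generator) -> PlotCovariates:
    """Draw one covariate row per plot.

    Soil texture comes from a Dirichlet over (sand, silt, clay), so silt and
    clay are proportions that never sum above 1.  Management intensities are
    yearly Poisson counts averaged over the study years.
    """
    n = design.n_plots
    lat = rng.uniform(*design.latitude_range, size=n)
    ph = rng.normal(*design.ph_mean_sd, size=n)
    texture = rng.dirichlet(design.texture_dirichlet, size=n)
    counts = {
        name: rng.poisson(mean, size=(n, design.n_years)).mean(axis=1)
        for name, mean in zip(["mowing", "tillage", "herbicide"], design.management_means)
    }
    table = pd.DataFrame(
        {
            "plot_id": [f"P{i:03d}" for i in range(n)],
            "latitude": lat,
            "pH": ph,
            "silt": texture[:, 1],
            "clay": texture[:, 2],
            **counts,
        }
    )
    return PlotCovariates(table)


def generate_traits(design: DesignSpec, rng: np.random.Generator) -> SpeciesTraits:
    """Seed masses log-uniform over the design range (mg)."""
    lo, hi = design.seed_mass_range_mg
    mass = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=design.n_species)
    table = pd.DataFrame(
        {"species_id": [f"S{j:03d}" for j in range(design.n_species)], "seed_mass": mass}
    )
    return SpeciesTraits(table)


def _simulate_series_batch(
    rng: np.random.Generator,
    p0: np.ndarray,
    g: np.ndarray,
    s: np.ndarray,
    c: np.ndarray,
    T: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized simulation of N independent chains for T years."""
    N = p0.size
    states = np.empty((N, T), dtype=np.int64)
    init = np.stack([build_initial(p0[i], g[i]) for i in range(N)])
    trans = np.stack([build_transition(g[i], s[i], c[i]) for i in range(N)])
    cum_init = np.cumsum(init, axis=1)
    cum_trans = np.cumsum(trans, axis=2)
    u = rng.random((N, T))
    states[:, 0] = (u[:, [0]] > cum_init).sum(axis=1)
    rows = np.arange(N)
    for t in range(1, T):
        states[:, t] = (u[:, [t]] > cum_trans[rows, states[:, t - 1]]).sum(axis=1)
    observations = (states == 2).astype(np.int64)
    return states, observations


def generate_dataset(design: DesignSpec) -> tuple[ModelDataset, dict]:
    """Generate a complete synthetic dataset and its latent truth.

    Returns the assembled model-ready dataset plus a truth record holding
    the hyperparameters, the drawn species coefficients and logit
    intercepts, per-species p0, the (plot, species) probability grids and
    the hidden seed-bank states — everything a recovery experiment needs.
    """
    rng = np.random.default_rng(design.seed)
    I, J, T = design.n_plots, design.n_species, design.n_years

    cov = standardize_covariates(generate_covariates(design, rng))
    traits = generate_traits(design, rng)
    trait_vec = traits.table["log_seed_mass_std"].to_numpy()
    D = np.column_stack(
        [np.ones(I), cov.table[COVARIATE_NAMES].to_numpy(dtype=float)]
    )

    focal = design.truth["focal"]
    hyper: HyperParams = design.truth["hyper"]
    means = hyper.coef_means(trait_vec)  # (J, 8)
    alpha = rng.normal(means, hyper.sigma[None, :])
    probs = {focal: expit(D @ alpha.T)}  # (I, J)
    eta = {}
    for p in PARAM_NAMES:
        if p == focal:
            continue
        mu, sd = design.truth["nuisance"][p]
        eta[p] = rng.normal(mu, sd, size=J)
        probs[p] = np.broadcast_to(expit(eta[p]), (I, J))
    p0 = rng.uniform(*design.truth.get("p0_range", (0.0, 1.0)), size=J)

    flat = lambda a: np.broadcast_to(a, (I, J)).ravel()
    states, obs = _simulate_series_batch(
        rng, flat(p0[None, :]), flat(probs["g"]), flat(probs["s"]), flat(probs["c"]), T
    )
    obs = obs.reshape(I, J, T)
    states = states.reshape(I, J, T)

    surveyed = rng.random((I, T)) >= design.missing_rate  # plot-year survey mask
    obs_masked = np.where(surveyed[:, None, :], obs, MISSING)

    years = list(range(design.years[0], design.years[1] + 1))
    dataset = ModelDataset(
        obs=obs_masked,
        X=cov.table[COVARIATE_NAMES].to_numpy(dtype=float),
        traits=trait_vec,
        plot_ids=list(cov.table["plot_id"]),
        species_ids=list(traits.table["species_id"]),
        years=years,
        covariates=cov,
        trait_table=traits,
    )
    truth = {
        "design": design,
        "hyper": hyper,
        "focal": focal,
        "alpha": alpha,
        "eta": eta,
        "p0": p0,
        "probs": probs,
        "hidden_states": states,
        "surveyed": surveyed,
    }
    return dataset, truth


def dataset_to_tables(
    dataset: ModelDataset,
) -> tuple[SurveyPanel, PlotCovariates, SpeciesTraits]:
    """Export a dataset back to the three long/wide CSV-able tables.

    Unsurveyed plot-years are dropped from the panel (they are implicit in
    the year range), so the round trip through ``assemble_dataset``
    reproduces the observation array exactly.
    """
    I, J, T = dataset.obs.shape
    ii, jj, tt = np.meshgrid(range(I), range(J), range(T), indexing="ij")
    present = dataset.obs.ravel()
    keep = present != MISSING
    panel = SurveyPanel(
        pd.DataFrame(
            {
                "plot_id": np.asarray(dataset.plot_ids)[ii.ravel()[keep]],
                "species_id": np.asarray(dataset.species_ids)[jj.ravel()[keep]],
                "year": np.asarray(dataset.years)[tt.ravel()[keep]],
                "present": present[keep],
            }
        )
    )
    return panel, dataset.covariates, dataset.trait_table
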