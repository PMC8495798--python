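"""Reading, validation and assembly of the three survey input tables.

Inputs are plain CSV:

* a long-format presence panel (``plot_id, species_id, year, present``),
  where ``present`` is 0/1 and a row may be absent for unsurveyed
  plot-years;
* a plot covariate table (latitude, soil pH, silt and clay fractions,
  mean annual counts of mowing, tillage and herbicide treatments);
* a species trait table with seed mass in mg.

Covariates are standardized (mean 0, sd 1 across plots) before entering
the logit-scale regression so slope magnitudes are comparable; seed mass
enters as centered/scaled log10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "COVARIATE_NAMES",
    "MANAGEMENT_NAMES",
    "SurveyPanel",
    "PlotCovariates",
    "SpeciesTraits",
    "ModelDataset",
    "read_panel",
    "write_panel",
    "read_covariates",
    "read_traits",
    "standardize_covariates",
    "assemble_dataset",
]

#: environmental + management covariates, in the order of the logit equation
COVARIATE_NAMES = ["latitude", "pH", "silt", "clay", "mowing", "tillage", "herbicide"]
MANAGEMENT_NAMES = ["mowing", "tillage", "herbicide"]

_PANEL_COLUMNS = ["plot_id", "species_id", "year", "present"]


@dataclass
class SurveyPanel:
    """Long-format presence-absence records, one row per observed (plot, species, year)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _PANEL_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"panel missing columns {missing}")
        dup = t.duplicated(subset=["plot_id", "species_id", "year"])
        if dup.any():
            rows = t.loc[dup, ["plot_id", "species_id", "year"]].head(5)
            raise ValueError(f"duplicate (plot, species, year) keys:\n{rows}")
        bad = ~t["present"].isin([0, 1]) & t["present"].notna()
        if bad.any():
            raise ValueError(
                f"present must be 0, 1 or NA; offending rows {list(t.index[bad][:5])}"
            )

    @property
    def plots(self) -> list:
        return sorted(self.table["plot_id"].unique())

    @property
    def species(self) -> list:
        return sorted(self.table["species_id"].unique())

    @property
    def n_surveys(self) -> int:
        """Number of distinct plot-year surveys with at least one record."""
        return self.table.dropna(subset=["present"])[["plot_id", "year"]].drop_duplicates().shape[0]


@dataclass
class PlotCovariates:
    """Per-plot covariates; ``scale`` holds (mean, sd) per column once standardized."""

    table: pd.DataFrame
    standardized: bool = False
    scale: dict[str, tuple[float, float]] = field(default_factory=dict)
    constant_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "plot_id" not in self.table.columns:
            raise ValueError("covariate table needs a plot_id column")
        missing = [c for c in COVARIATE_NAMES if c not in self.table.columns]
        if missing:
            raise ValueError(f"covariate table missing columns {missing}")
        if self.table["plot_id"].duplicated().any():
            raise ValueError("covariate table has duplicate plot_id rows")


@dataclass
class SpeciesTraits:
    """Seed mass (mg) per species plus its centered/scaled log10 transform."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("species_id", "seed_mass"):
            if col not in t.columns:
                raise ValueError(f"trait table needs a {col} column")
        if len(t) == 0:
            raise ValueError("trait table is empty")
        if t["species_id"].duplicated().any():
            raise ValueError("trait table has duplicate species_id rows")
        if (t["seed_mass"] <= 0).any():
            raise ValueError("seed_mass must be positive (mg)")
        if "log_seed_mass_std" not in t.columns:
            logmass = np.log10(t["seed_mass"].to_numpy(dtype=float))
            sd = logmass.std()
            if sd == 0.0:
                self.table = t.assign(log_seed_mass_std=0.0)
            else:
                self.table = t.assign(log_seed_mass_std=(logmass - logmass.mean()) / sd)


@dataclass
class ModelDataset:
    """Model-ready arrays: rectangular series plus aligned covariates and traits.

    Attributes
    ----------
    obs : int array, shape (n_plots, n_species, n_years)
        0/1 presence, ``MISSING`` for unsurveyed plot-years.
    X : float array, shape (n_plots, 7)
        Standardized covariates in ``COVARIATE_NAMES`` order.
    traits : float array, shape (n_species,)
        Centered/scaled log10 seed mass.
    """

    obs: np.ndarray
    X: np.ndarray
    traits: np.ndarray
    plot_ids: list
    species_ids: list
    years: list
    covariates: PlotCovariates = None
    trait_table: SpeciesTraits = None

    @property
    def n_plots(self) -> int:
        return self.obs.shape[0]

    @property
    def n_species(self) -> int:
        return self.obs.shape[1]

    @property
    def n_years(self) -> int:
        return self.obs.shape[2]

    def design_matrix(self) -> np.ndarray:
        """(n_plots, 8) matrix: intercept column then the 7 standardized covariates."""
        return np.column_stack([np.ones(self.n_plots), self.X])


def read_panel(path) -> SurveyPanel:
    """Read and validate a long-format presence panel CSV."""
    table = pd.read_csv(path)
    try:
        table["year"] = table["year"].astype(int)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed year column in {path}: {exc}") from exc
    return SurveyPanel(table)


def write_panel(panel: SurveyPanel, path) -> None:
    panel.table.to_csv(path, index=False)


def read_covariates(path) -> PlotCovariates:
    """Read the plot covariate CSV; silt/clay > 1 are taken as percent and rescaled."""
    table = pd.read_csv(path)
    cov = PlotCovariates(table)
    for col in ("silt", "clay"):
        if (cov.table[col] > 1.0).any():
            logger.info("column %s looks like percent; converting to proportion", col)
            cov.table[col] = cov.table[col] / 100.0
    return cov


def read_traits(path) -> SpeciesTraits:
    return SpeciesTraits(pd.read_csv(path))


def aggregate_management_years(table: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Collapse year-wise management records to one row per plot.

    Management differs between years on the same plot, but the regression
    indexes practices by plot only; ``how='mean'`` (default) takes the mean
    annual count over the recorded years, ``how='total'`` the total count.
    Non-management columns must be constant within a plot and pass through.
    """
    if how not in ("mean", "total"):
        raise ValueError("how must be 'mean' or 'total'")
    agg = "mean" if how == "mean" else "sum"
    others = [c for c in table.columns if c not in MANAGEMENT_NAMES + ["plot_id", "year"]]
    grouped = table.groupby("plot_id", sort=True)
    for col in others:
        if (grouped[col].nunique() > 1).any():
            raise ValueError(f"column {col} varies within a plot; cannot aggregate")
    out = grouped.agg({**{c: agg for c in MANAGEMENT_NAMES}, **{c: "first" for c in others}})
    return out.reset_index()[["plot_id", *others, *MANAGEMENT_NAMES]]


def standardize_covariates(cov: PlotCovariates) -> PlotCovariates:
    """Center and scale each covariate to mean 0, sd 1 (population sd).

    Constant covariates cannot be scaled; they are set to zero and recorded
    in ``constant_flags`` with a warning.  Idempotent: standardizing twice
    changes nothing beyond round-off.
    """
    table = cov.table.copy()
    scale: dict[str, tuple[float, float]] = dict(cov.scale)
    flags = list(cov.constant_flags)
    if len(table) < 2:
        raise ValueError("need at least 2 plots to standardize covariates")
    for col in COVARIATE_NAMES:
        x = table[col].to_numpy(dtype=float)
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0.0:
            if col not in flags:
                logger.warning("covariate %s is constant; set to 0 and flagged", col)
                flags.append(col)
            table[col] = 0.0
            scale.setdefault(col, (mu, 0.0))
        else:
            table[col] = (x - mu) / sd
            if col not in cov.scale:  # keep the original (mean, sd) on re-standardization
                scale[col] = (mu, sd)
    return PlotCovariates(table, standardized=True, scale=scale, constant_flags=flags)


def assemble_dataset(
    panel: SurveyPanel,
    cov: PlotCovariates,
    traits: SpeciesTraits,
    year_range: tuple[int, int] | None = None,
) -> ModelDataset:
    """Pivot the panel to rectangular (plot, species, year) series and align tables.

    Every (plot, species) series spans the full ``year_range`` with explicit
    ``MISSING`` entries for unsurveyed plot-years; missingness is survey
    level, i.e. identical across species within a plot-year.
    """
    if not cov.standardized:
        cov = standardize_covariates(cov)
    t = panel.table
    if year_range is None:
        year_range = (int(t["year"].min()), int(t["year"].max()))
    years = list(range(year_range[0], year_range[1] + 1))
    if not set(t["year"]).issubset(years):
        raise ValueError("panel contains years outside year_range")

    plot_ids = panel.plots
    species_ids = panel.species
    missing_plots = sorted(set(plot_ids) - set(cov.table["plot_id"]))
    if missing_plots:
        raise ValueError(f"plots missing from covariate table: {missing_plots}")
    missing_species = sorted(set(species_ids) - set(traits.table["species_id"]))
    if missing_species:
        raise ValueError(f"species missing from trait table: {missing_species}")

    n_i, n_j, n_t = len(plot_ids), len(species_ids), len(years)
    obs = np.full((n_i, n_j, n_t), MISSING, dtype=np.int64)
    pi = {p: k for k, p in enumerate(plot_ids)}
    si = {s: k for k, s in enumerate(species_ids)}
    yi = {y: k for k, y in enumerate(years)}
    observed = t.dropna(subset=["present"])
    obs[
        observed["plot_id"].map(pi).to_numpy(),
        observed["species_id"].map(si).to_numpy(),
        observed["year"].map(yi).to_numpy(),
    ] = observed["present"].to_numpy(dtype=np.int64)

    cov_sorted = cov.table.set_index("plot_id").loc[plot_ids]
    X = cov_sorted[COVARIATE_NAMES].to_numpy(dtype=float)
    tr_sorted = traits.table.set_index("species_id").loc[species_ids]
    trait_vec = tr_sorted["log_seed_mass_std"].to_numpy(dtype=float)

    return ModelDataset(
        obs=obs,
        X=X,
        traits=trait_vec,
        plot_ids=plot_ids,
        species_ids=species_ids,
        years=years,
        covariates=cov,
        trait_table=traits,
    )
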