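"""Link function, random-effect structure, posterior density and the sampler."""

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

from seedbankhmm import (
    DemographicParams,
    DesignSpec,
    HyperParams,
    ModelDataset,
    ModelSpec,
    fit,
    forward_loglik,
    generate_dataset,
    link_theta,
    log_posterior,
    species_effect_mean,
)


def _hyper(**kw):
    base = dict(
        alpha_bar=np.zeros(5), gamma=np.zeros(3), beta=np.zeros(3), sigma=np.ones(8)
    )
    base.update(kw)
    return HyperParams(**base)


class TestLink:
    def test_zero_effects_give_half(self):
        assert link_theta(np.zeros(8), np.array([1.3, -0.2, 0.5, 2.0, 0.1, -1.0, 0.7])) == 0.5

    def test_intercept_only_at_covariate_means(self):
        eff = np.zeros(8)
        eff[0] = logit(0.8)
        assert link_theta(eff, np.zeros(7)) == pytest.approx(0.8)

    def test_tillage_coefficient(self):
        eff = np.zeros(8)
        eff[6] = 1.0  # tillage coefficient
        cov = np.zeros(7)
        cov[5] = 2.0  # tillage z-score
        assert link_theta(eff, cov) == pytest.approx(expit(2.0))
        assert link_theta(eff, cov) == pytest.approx(0.8808, abs=1e-4)

    def test_nonfinite_predictor_rejected(self):
        with pytest.raises(ValueError):
            link_theta(np.full(8, np.nan), np.zeros(7))


class TestSpeciesEffectMean:
    def test_environmental_ignores_trait(self):
        h = _hyper(alpha_bar=np.array([0.0, 0.0, 0.3, 0.0, 0.0]))
        assert species_effect_mean(2, h, trait=5.0) == 0.3

    def test_management_is_linear_in_trait(self):
        h = _hyper(gamma=np.array([0.0, 0.0, 0.1]), beta=np.array([0.0, 0.0, 0.5]))
        assert species_effect_mean(7, h, trait=1.0) == pytest.approx(0.6)

    def test_zero_slope_collapses_to_exchangeable(self):
        h = _hyper(gamma=np.array([0.2, 0.2, 0.2]))
        means = [species_effect_mean(5, h, trait=t) for t in (-2.0, 0.0, 2.0)]
        assert len(set(means)) == 1

    def test_invalid_index(self):
        with pytest.raises(ValueError):
            species_effect_mean(8, _hyper())


def test_hyperparams_validation():
    with pytest.raises(ValueError):
        HyperParams(np.zeros(4), np.zeros(3), np.zeros(3), np.ones(8))
    with pytest.raises(ValueError):
        HyperParams(np.zeros(5), np.zeros(3), np.zeros(3), -np.ones(8))


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(focal="x")
    with pytest.raises(ValueError):
        ModelSpec(iterations=100, burn_in=100)
    assert ModelSpec(focal="s").nuisance == ("g", "c")
    assert ModelSpec(joint=True).structured == ("g", "s", "c")


# ---------------------------------------------------------------------------
# log_posterior


def _state(dataset, spec, rng):
    J = dataset.n_species
    state = {
        f"{spec.focal}_alpha": rng.normal(0, 0.5, (J, 8)),
        f"{spec.focal}_alpha_bar": rng.normal(0, 0.5, 5),
        f"{spec.focal}_gamma": rng.normal(0, 0.5, 3),
        f"{spec.focal}_beta": rng.normal(0, 0.5, 3),
        f"{spec.focal}_sigma": rng.uniform(0.2, 1.0, 8),
        "p0": rng.uniform(0.1, 0.9, J),
    }
    for p in spec.nuisance:
        state[f"{p}_eta"] = rng.normal(0, 0.5, J)
        state[f"{p}_mu"] = rng.normal(0, 0.5)
        state[f"{p}_tau"] = rng.uniform(0.2, 1.0)
    return state


def _naive_log_posterior(dataset, state, spec):
    """Independent per-series recomputation, scalar forward, explicit priors."""
    D = dataset.design_matrix()
    lp = 0.0
    focal = spec.focal
    for i in range(dataset.n_plots):
        for j in range(dataset.n_species):
            probs = {focal: float(expit(D[i] @ state[f"{focal}_alpha"][j]))}
            for p in spec.nuisance:
                probs[p] = float(expit(state[f"{p}_eta"][j]))
            params = DemographicParams(
                p0=float(state["p0"][j]), g=probs["g"], s=probs["s"], c=probs["c"]
            )
            lp += forward_loglik(dataset.obs[i, j], params)
    h = HyperParams(
        state[f"{focal}_alpha_bar"],
        state[f"{focal}_gamma"],
        state[f"{focal}_beta"],
        state[f"{focal}_sigma"],
    )
    means = h.coef_means(dataset.traits)
    lp += norm.logpdf(state[f"{focal}_alpha"], means, h.sigma[None, :]).sum()
    for v in (h.alpha_bar, h.gamma, h.beta):
        lp += norm.logpdf(v, 0, spec.prior_coef_sd).sum()
    lp += -8 * np.log(spec.sigma_upper)
    for p in spec.nuisance:
        lp += norm.logpdf(state[f"{p}_eta"], state[f"{p}_mu"], state[f"{p}_tau"]).sum()
        lp += norm.logpdf(state[f"{p}_mu"], 0, spec.prior_coef_sd)
        lp += -np.log(spec.sigma_upper)
    return lp


class TestLogPosterior:
    def test_matches_naive_recomputation(self, small_dataset, rng):
        dataset, _ = small_dataset
        spec = ModelSpec()
        state = _state(dataset, spec, rng)
        assert log_posterior(dataset, state, spec) == pytest.approx(
            _naive_log_posterior(dataset, state, spec), abs=1e-8
        )

    def test_likelihood_additivity_under_dataset_doubling(self, small_dataset, rng):
        dataset, _ = small_dataset
        spec = ModelSpec()
        state = _state(dataset, spec, rng)
        doubled = ModelDataset(
            obs=np.concatenate([dataset.obs, dataset.obs], axis=0),
            X=np.concatenate([dataset.X, dataset.X], axis=0),
            traits=dataset.traits,
            plot_ids=dataset.plot_ids + [f"{p}_copy" for p in dataset.plot_ids],
            species_ids=dataset.species_ids,
            years=dataset.years,
        )
        lp1 = log_posterior(dataset, state, spec)
        lp2 = log_posterior(doubled, state, spec)
        # same prior term, so the difference is exactly the likelihood term
        prior = log_posterior(
            ModelDataset(
                obs=np.full_like(dataset.obs, -1),
                X=dataset.X,
                traits=dataset.traits,
                plot_ids=dataset.plot_ids,
                species_ids=dataset.species_ids,
                years=dataset.years,
            ),
            state,
            spec,
        )
        assert lp2 - lp1 == pytest.approx(lp1 - prior, abs=1e-8)

    def test_flat_data_reduces_to_prior(self, small_dataset, rng):
        """All-absent panel with p0 and c pinned near 0: the likelihood is ~1."""
        dataset, _ = small_dataset
        spec = ModelSpec()
        state = _state(dataset, spec, rng)
        absent = ModelDataset(
            obs=np.zeros_like(dataset.obs),
            X=dataset.X,
            traits=dataset.traits,
            plot_ids=dataset.plot_ids,
            species_ids=dataset.species_ids,
            years=dataset.years,
        )
        state["p0"] = np.full(dataset.n_species, 1e-12)
        state["c_eta"] = np.full(dataset.n_species, -40.0)
        lp = log_posterior(absent, state, spec)
        prior = _naive_log_posterior(
            ModelDataset(
                obs=np.full_like(dataset.obs, -1),
                X=dataset.X,
                traits=dataset.traits,
                plot_ids=dataset.plot_ids,
                species_ids=dataset.species_ids,
                years=dataset.years,
            ),
            state,
            spec,
        )
        assert lp == pytest.approx(prior, abs=1e-6)

    def test_sigma_outside_support_is_minus_inf(self, small_dataset, rng):
        dataset, _ = small_dataset
        spec = ModelSpec()
        state = _state(dataset, spec, rng)
        state["g_sigma"] = np.full(8, 6.0)  # beyond Uniform(0, 5)
        assert log_posterior(dataset, state, spec) == -np.inf

    def test_species_permutation_invariance(self, small_dataset, rng):
        """Permuting species together with their traits and data leaves the
        posterior density unchanged (species are exchangeable)."""
        dataset, _ = small_dataset
        spec = ModelSpec()
        state = _state(dataset, spec, rng)
        perm = rng.permutation(dataset.n_species)
        permuted = ModelDataset(
            obs=dataset.obs[:, perm, :],
            X=dataset.X,
            traits=dataset.traits[perm],
            plot_ids=dataset.plot_ids,
            species_ids=[dataset.species_ids[j] for j in perm],
            years=dataset.years,
        )
        pstate = dict(state)
        for key in ("g_alpha", "s_eta", "c_eta", "p0"):
            pstate[key] = state[key][perm]
        assert log_posterior(permuted, pstate, spec) == pytest.approx(
            log_posterior(dataset, state, spec), abs=1e-10
        )

    def test_prior_predictive_never_nan(self, rng):
        dataset, _ = generate_dataset(DesignSpec.small(seed=5))
        spec = ModelSpec()
        for _ in range(20):
            lp = log_posterior(dataset, _state(dataset, spec, rng), spec)
            assert np.isfinite(lp)


# ---------------------------------------------------------------------------
# the sampler


class TestFit:
    def test_tiny_fit_runs_and_is_finite(self):
        dataset, _ = generate_dataset(
            DesignSpec(n_plots=3, n_species=2, years=(2006, 2009), seed=17)
        )
        draws = fit(dataset, ModelSpec(iterations=500, burn_in=100, seed=3))
        for name, arr in draws.draws.items():
            assert np.all(np.isfinite(arr)), name
        assert draws.draws["g_alpha"].shape == (2, 500, 2, 8)
        assert np.all(draws.draws["p0"] > 0) and np.all(draws.draws["p0"] < 1)
        assert np.all(draws.draws["g_sigma"] <= 5.0)

    def test_reproducible_given_seed(self):
        dataset, _ = generate_dataset(
            DesignSpec(n_plots=3, n_species=2, years=(2006, 2009), seed=17)
        )
        spec = ModelSpec(iterations=120, burn_in=40, seed=9)
        d1 = fit(dataset, spec)
        d2 = fit(dataset, spec)
        for name in d1.draws:
            np.testing.assert_array_equal(d1.draws[name], d2.draws[name])

    def test_chains_start_overdispersed(self, small_fit):
        draws, _, _ = small_fit
        first = draws.draws["g_alpha_bar"][:, 0, :]
        assert not np.allclose(first[0], first[1])

    def test_draws_round_trip_dataframe(self, small_fit, tmp_path):
        from seedbankhmm import PosteriorDraws

        draws, _, _ = small_fit
        df = draws.to_dataframe()
        assert {"chain", "iteration"} <= set(df.columns)
        assert len(df) == 2 * 400
        draws.save(tmp_path / "d.csv", tmp_path / "d.json")
        again = PosteriorDraws.load(tmp_path / "d.csv", tmp_path / "d.json")
        assert again.spec == draws.spec
        for name in draws.draws:
            np.testing.assert_allclose(again.draws[name], draws.draws[name], atol=1e-12)
        np.testing.assert_allclose(again.traits, draws.traits, atol=1e-12)
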