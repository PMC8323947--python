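"""Core model math: Poisson mean, likelihood, latent density, priors."""

import math

import numpy as np
import pytest
from scipy.stats import norm, poisson

from countflux import (
    ModelSpec,
    ParameterState,
    PriorSpec,
    log_latent_density,
    log_likelihood,
    log_prior,
    poisson_mean,
    simulate_counts,
    simulate_latent,
)
from countflux.exceptions import ValidationError


def params(beta, rho=0.0, sigma=1.0, delta0=0.0):
    return ParameterState(beta=np.atleast_1d(beta), rho=rho, sigma=sigma, delta0=delta0)


class TestSimulateLatent:
    def test_identity_recursion(self):
        np.testing.assert_allclose(simulate_latent(1.0, 0.0, 2.0, 3), [2, 2, 2])

    def test_geometric_decay(self):
        np.testing.assert_allclose(simulate_latent(0.5, 0.0, 4.0, 3), [2, 1, 0.5])

    def test_stationary_variance(self):
        # AR(1): var = sigma^2 / (1 - rho^2) = 0.09 / 0.19
        path = simulate_latent(0.9, 0.3, 0.0, 100_000, seed=7)
        assert np.var(path) == pytest.approx(0.09 / 0.19, rel=0.05)

    def test_t_below_one_rejected(self):
        with pytest.raises(ValidationError):
            simulate_latent(0.5, 1.0, 0.0, 0)


class TestPoissonMean:
    def test_exponent_of_zero(self):
        assert poisson_mean(2.0, [0.0], [0.0], 0.0) == pytest.approx(2.0)

    def test_single_coefficient(self):
        assert poisson_mean(1.0, [1.0], [0.5], 0.0) == pytest.approx(
            math.exp(0.5), rel=1e-9
        )

    def test_zero_exposure_forces_zero_mean(self):
        assert poisson_mean(0.0, [3.0], [10.0], 5.0) == 0.0

    def test_vectorised_matches_scalar(self, rng):
        b = rng.integers(0, 5, 20).astype(float)
        X = rng.normal(size=(20, 2))
        beta = np.array([0.3, -0.7])
        delta = rng.normal(size=20)
        lam = poisson_mean(b, X, beta, delta)
        expect = b * np.exp(X @ beta + delta)
        np.testing.assert_allclose(lam, expect, rtol=1e-12)


class TestLogLikelihood:
    def test_zero_count_unit_mean(self):
        ll = log_likelihood(([0], [1]), np.ones((1, 1)), params([0.0]), [0.0])
        assert ll == pytest.approx(-1.0, abs=1e-10)

    def test_two_counts_mean_two(self):
        ll = log_likelihood(([2], [2]), np.ones((1, 1)), params([0.0]), [0.0])
        assert ll == pytest.approx(math.log(2) - 2, abs=1e-10)

    def test_positive_count_zero_exposure_impossible(self):
        ll = log_likelihood(([1], [0]), np.ones((1, 1)), params([0.0]), [0.0])
        assert ll == -math.inf

    def test_matches_scipy_poisson_logpmf(self, rng):
        T = 30
        b = rng.integers(1, 6, T).astype(float)
        X = np.column_stack([np.ones(T), rng.normal(size=T)])
        beta = np.array([0.2, 0.8])
        delta = 0.3 * rng.normal(size=T)
        y = rng.poisson(2.0, T)
        lam = b * np.exp(X @ beta + delta)
        expect = poisson.logpmf(y, lam).sum()
        got = log_likelihood((y, b), X, params(beta), delta)
        assert got == pytest.approx(expect, abs=1e-8)

    def test_reduces_to_poisson_glm_with_offset(self, rng):
        # with delta = 0 the model is an ordinary Poisson GLM with log(b) offset
        import statsmodels.api as sm

        T = 200
        b = rng.integers(1, 8, T).astype(float)
        x = rng.normal(size=T)
        X = np.column_stack([np.ones(T), x])
        y = rng.poisson(b * np.exp(0.1 + 0.5 * x))
        fit = sm.GLM(
            y, X, family=sm.families.Poisson(), offset=np.log(b)
        ).fit()
        ours = log_likelihood((y, b), X, params(fit.params), np.zeros(T))
        assert ours == pytest.approx(fit.llf, abs=1e-8)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            log_likelihood(([1, 2], [1, 1]), np.ones((2, 1)), params([0.0]), [0.0])


class TestLogLatentDensity:
    def test_standard_normal_at_zero(self):
        val = log_latent_density([0.0], rho=0.0, sigma=1.0, delta0=0.0)
        assert val == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)), abs=1e-10)

    def test_deterministic_path_any_sigma(self):
        rho, d0, sigma, T = 0.7, 1.3, 0.42, 6
        path = [d0 * rho ** (t + 1) for t in range(T)]
        val = log_latent_density(path, rho, sigma, d0)
        assert val == pytest.approx(
            T * math.log(1 / (sigma * math.sqrt(2 * math.pi))), rel=1e-12
        )

    def test_markov_locality_of_perturbation(self, rng):
        path = rng.normal(size=10)
        base = log_latent_density(path, 0.6, 0.5, 0.0)
        bumped = path.copy()
        bumped[4] += 0.1
        changed = log_latent_density(bumped, 0.6, 0.5, 0.0)
        # only terms 4 and 5 move; recompute them directly
        def term(t, p):
            prev = p[t - 1] if t > 0 else 0.0
            return norm.logpdf(p[t], 0.6 * prev, 0.5)

        expect = base - term(4, path) - term(5, path) + term(4, bumped) + term(5, bumped)
        assert changed == pytest.approx(expect, abs=1e-10)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            log_latent_density([0.0], 0.0, 0.0, 0.0)


class TestLogPrior:
    def test_exponential_contribution(self):
        pri = PriorSpec()
        base = log_prior(params([0.0], sigma=1.0), pri)
        # sigma term alone: log 0.7 - 0.7
        other = (
            norm.logpdf(0, 0, 1)
            + norm.logpdf(0, 0, pri.rho_sd)
            + norm.logpdf(0, 0, pri.delta0_sd)
        )
        assert base - other == pytest.approx(math.log(0.7) - 0.7, abs=1e-10)

    def test_beta_component_standard_normal_at_zero(self):
        pri = PriorSpec()
        one = log_prior(params([0.0], sigma=1.0), pri)
        two = log_prior(params([0.0, 0.0], sigma=1.0), pri)
        assert two - one == pytest.approx(-0.9189385, abs=1e-6)

    def test_negative_sigma_is_outside_support(self):
        state = params([0.0], sigma=1.0)
        state.sigma = -1.0  # bypass the constructor guard on purpose
        assert log_prior(state, PriorSpec()) == -math.inf

    def test_prior_predictive_intensity_bound(self):
        # P(e^beta > 5) under the default coefficient prior stays below 6%
        pri = PriorSpec()
        p = norm.sf(math.log(5.0), loc=pri.beta_mean, scale=pri.beta_sd)
        assert p < 0.06


class TestModelSpecs:
    def test_four_presets_free_masks(self):
        masks = {
            name: ModelSpec.from_preset(name).free_mask
            for name in ("baseline", "temperature", "rainfall", "combined")
        }
        assert masks == {
            "baseline": (False, False),
            "temperature": (True, False),
            "rainfall": (False, True),
            "combined": (True, True),
        }

    def test_parameter_labels_include_intercept_first(self):
        spec = ModelSpec.from_preset("combined")
        assert spec.parameter_labels == (
            "intercept",
            "beta_temperature",
            "beta_rainfall",
            "rho",
            "sigma",
            "delta0",
        )

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec.from_preset("kitchen_sink")

    def test_widened_priors_scale_all_sds(self):
        wide = PriorSpec().widened(10.0)
        assert wide.beta_sd == pytest.approx(10.0)
        assert wide.rho_sd == pytest.approx(math.sqrt(10) * 10)
        assert wide.sigma_rate == pytest.approx(0.07)


class TestSimulateCounts:
    def test_zero_mean_everywhere_gives_zero_counts(self):
        y = simulate_counts(
            np.zeros((5, 1)), np.zeros(5), params([0.0, 0.0]), np.zeros(5), seed=0
        )
        assert (y == 0).all()

    def test_fixed_seed_reproducible(self):
        args = (np.zeros((5, 1)), np.ones(5), params([1.0, 0.0]), np.zeros(5))
        np.testing.assert_array_equal(
            simulate_counts(*args, seed=42), simulate_counts(*args, seed=42)
        )

    def test_long_run_mean(self):
        # 1e5 draws at lambda = 3
        lam3 = math.log(3.0)
        y = simulate_counts(
            np.zeros((100_000, 1)),
            np.ones(100_000),
            params([lam3, 0.0]),
            np.zeros(100_000),
            seed=5,
        )
        assert y.mean() == pytest.approx(3.0, abs=0.02)


def test_joint_density_peaks_near_truth_on_average(rng):
    """Joint log density at the generating values beats perturbed values."""
    from countflux import SyntheticConfig, generate_dataset

    wins = 0
    for rep in range(10):
        ds, truth = generate_dataset(SyntheticConfig(n_years=150, seed=200 + rep))
        p = truth["params"]
        X = np.column_stack(
            [np.ones(ds.n_years)]
            + [
                ds.covariates[c] - ds.covariates[c].mean()
                for c in ds.covariate_names
            ]
        )
        def joint(pp, lat):
            return (
                log_likelihood(ds, X, pp, lat)
                + log_latent_density(lat, pp.rho, pp.sigma, pp.delta0)
                + log_prior(pp, PriorSpec())
            )

        at_truth = joint(p, truth["delta"])
        assert np.isfinite(at_truth)
        perturbed = ParameterState(
            beta=p.beta + 1.0, rho=p.rho - 0.5, sigma=p.sigma * 3, delta0=p.delta0 + 2
        )
        if at_truth > joint(perturbed, truth["delta"]):
            wins += 1
    assert wins >= 8
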