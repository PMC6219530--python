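"""Per-trial decision rules: MLE, MAP, PM, AS and the box-prior variant."""

import math

import numpy as np
import pytest

from soundloc.bayes_core import GaussianBelief, NoiseModel, map_gain, posterior_sd
from soundloc.decision_rules import (
    DecisionConfig,
    apply_scheme,
    decide_as,
    decide_map,
    decide_map_box,
    decide_mle,
    decide_pm,
    estimate_sampling_halfwidth,
    posterior_for_trial,
    sample_likelihood_peak,
)

PRIOR = GaussianBelief(0.0, 11.5)


class TestLikelihoodPeak:
    def test_zero_noise_is_exact(self, rng):
        assert sample_likelihood_peak(-11.7, NoiseModel(0.0), rng) == -11.7

    def test_large_sample_moments(self, rng):
        """eps* scatters around the target with SD sigma_T (law of large numbers)."""
        draws = sample_likelihood_peak(10.0, NoiseModel(8.0), rng, size=100_000)
        assert draws.mean() == pytest.approx(10.0, abs=0.1)
        assert draws.std() == pytest.approx(8.0, abs=0.1)

    def test_vector_targets_get_independent_noise(self, rng):
        targets = np.zeros(1000)
        draws = sample_likelihood_peak(targets, NoiseModel(8.0), rng)
        assert draws.shape == (1000,)
        assert np.unique(draws).size == 1000  # not one shared noise sample


class TestPointRules:
    def test_mle_is_identity(self):
        assert decide_mle(-6.3) == -6.3
        assert decide_mle(0.0) == 0.0

    def test_map_returns_posterior_mean(self):
        assert decide_map(GaussianBelief(-4.3, 6.5)) == -4.3
        assert decide_map(GaussianBelief(0.0, 3.0)) == 0.0

    def test_map_equals_grid_argmax(self):
        """The analytic posterior mode equals a dense-grid argmax of the density."""
        post = posterior_for_trial(-6.3, NoiseModel(8.0), PRIOR)
        x = np.linspace(-60, 60, 2_400_001)
        dens = np.exp(-0.5 * ((x - post.mean) / post.sd) ** 2)
        assert decide_map(post) == pytest.approx(x[np.argmax(dens)], abs=1e-4)

    def test_box_prior_clips_the_mle(self):
        assert decide_map_box(20.0, 35.0) == 20.0
        assert decide_map_box(50.0, 35.0) == 35.0
        assert decide_map_box(-80.0, 35.0) == -35.0


class TestPosteriorMatching:
    def test_degenerate_posterior_returns_mean(self, rng):
        assert decide_pm(GaussianBelief(-4.3, np.finfo(float).tiny), rng) == -4.3

    def test_sample_moments_match_posterior(self, rng):
        draws = np.array([decide_pm(GaussianBelief(-4.3, 6.5), rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(-4.3, abs=0.15)
        assert draws.std() == pytest.approx(6.5, abs=0.12)


class TestSamplingHalfwidth:
    def test_recovers_sensory_noise(self):
        """sigma_hat reconstructs sigma_T exactly from the two widths."""
        for sigma_T in (1.0, 8.0, 40.0):
            s_post = posterior_sd(sigma_T, 11.5)
            h = estimate_sampling_halfwidth(s_post, 11.5, w0=0.9)
            assert h == pytest.approx(0.9 * sigma_T, rel=1e-9)

    def test_worked_values(self):
        assert estimate_sampling_halfwidth(6.5, 11.5, 0.9) == pytest.approx(
            0.9 * math.sqrt(6.5**2 / (1 - 6.5**2 / 11.5**2))
        )
        assert estimate_sampling_halfwidth(0.0, 11.5) == 0.0

    def test_divergence_signal(self):
        assert math.isinf(estimate_sampling_halfwidth(11.5, 11.5))
        assert math.isinf(estimate_sampling_halfwidth(12.0, 11.5))


class TestAdaptiveSampling:
    def test_zero_width_returns_map(self, rng):
        post = GaussianBelief(-4.3, np.finfo(float).tiny)
        assert decide_as(post, PRIOR, DecisionConfig(scheme="AS"), rng) == -4.3

    def test_no_evidence_falls_back_to_posterior_draw(self, rng):
        """Posterior as wide as the prior: AS samples the full posterior (= prior)."""
        draws = np.array(
            [decide_as(PRIOR, PRIOR, DecisionConfig(scheme="AS"), rng) for _ in range(20_000)]
        )
        assert draws.mean() == pytest.approx(0.0, abs=0.25)
        assert draws.std() == pytest.approx(11.5, abs=0.25)

    def test_draws_confined_to_window(self, rng):
        post = posterior_for_trial(-6.3, NoiseModel(8.0), PRIOR)
        h = estimate_sampling_halfwidth(post.sd, PRIOR.sd, 0.9)
        for law in ("truncated", "uniform"):
            cfg = DecisionConfig(scheme="AS", as_law=law)
            draws = np.array([decide_as(post, PRIOR, cfg, rng) for _ in range(2000)])
            assert np.all(np.abs(draws - post.mean) <= h + 1e-12)

    def test_w0_limits_interpolate_map_to_pm(self, rng):
        """Tiny w0 reproduces MAP statistics; huge w0 reproduces PM statistics."""
        sigma_T = 8.0
        noise = NoiseModel(sigma_T)
        eps = sample_likelihood_peak(np.zeros(40_000), noise, rng)
        g = map_gain(sigma_T, PRIOR.sd)
        narrow = apply_scheme(eps, noise, PRIOR, DecisionConfig(scheme="AS", w0=1e-6), rng)
        assert narrow.std() == pytest.approx(g * sigma_T, rel=0.03)  # sigma_MAP
        wide = apply_scheme(eps, noise, PRIOR, DecisionConfig(scheme="AS", w0=50.0), rng)
        pm_sd = math.sqrt((g * sigma_T) ** 2 + g * sigma_T**2)  # sigma_MAP^2 + sigma_POST^2
        assert wide.std() == pytest.approx(pm_sd, rel=0.03)


class TestApplyScheme:
    def test_zero_noise_collapses_all_schemes(self, rng):
        eps = np.array([-20.0, 0.0, 30.0])
        for scheme in ("MLE", "MAP", "PM", "AS"):
            out = apply_scheme(eps, NoiseModel(0.0), PRIOR, DecisionConfig(scheme=scheme), rng)
            np.testing.assert_array_equal(out, eps)

    def test_map_is_gain_times_estimate(self, rng):
        eps = np.linspace(-35, 35, 11)
        out = apply_scheme(eps, NoiseModel(8.0), PRIOR, DecisionConfig(scheme="MAP"), rng)
        np.testing.assert_allclose(out, map_gain(8.0, 11.5) * eps, rtol=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DecisionConfig(scheme="BOGUS")
        with pytest.raises(ValueError):
            DecisionConfig(w0=0.0)
        with pytest.raises(ValueError):
            DecisionConfig(as_law="nope")
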