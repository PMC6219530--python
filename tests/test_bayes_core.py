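"""Gaussian belief algebra and the closed-form gain-variance curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soundloc.bayes_core import (
    GaussianBelief,
    NoiseModel,
    SpatialPrior,
    UndefinedBeliefError,
    as_gain_curve,
    map_gain,
    map_response_sd,
    map_sigma_curve,
    pm_gain_curve,
    posterior_combine,
    posterior_sd,
)

finite_means = st.floats(-90, 90)
sds = st.floats(0.5, 80)


def grid_posterior_oracle(likelihood, prior, lo=-200.0, hi=200.0, n=400_001):
    """Brute-force posterior by gridding the product of the two densities."""
    x = np.linspace(lo, hi, n)
    log_post = (
        -0.5 * ((x - likelihood.mean) / likelihood.sd) ** 2
        - 0.5 * ((x - prior.mean) / prior.sd) ** 2
    )
    w = np.exp(log_post - log_post.max())
    w /= np.trapezoid(w, x)
    mean = np.trapezoid(w * x, x)
    var = np.trapezoid(w * (x - mean) ** 2, x)
    return mean, math.sqrt(var)


class TestPosteriorCombine:
    def test_worked_example(self):
        """The Fig-2A-style single trial: shrinkage towards the zero-mean prior."""
        post = posterior_combine(GaussianBelief(-6.3, 8.0), GaussianBelief(0.0, 11.5))
        assert post.mean == pytest.approx(-6.3 / (1 + 64 / 132.25))
        assert post.sd == pytest.approx(math.sqrt(64 / (1 + 64 / 132.25)))
        # printed rounded values of the worked example agree at 0.1 deg
        assert post.mean == pytest.approx(-4.3, abs=0.1)
        assert post.sd == pytest.approx(6.5, abs=0.1)

    def test_flat_prior_is_identity(self):
        lik = GaussianBelief(-6.3, 8.0)
        assert posterior_combine(lik, GaussianBelief(0.0, math.inf)) == lik
        assert posterior_combine(GaussianBelief(0.0, math.inf), lik) == lik

    def test_equal_widths_halve_mean(self):
        post = posterior_combine(GaussianBelief(10.0, 6.0), GaussianBelief(0.0, 6.0))
        assert post.mean == pytest.approx(5.0)
        assert post.sd == pytest.approx(6.0 / math.sqrt(2))

    def test_two_flat_beliefs_error(self):
        flat = GaussianBelief(0.0, math.inf)
        with pytest.raises(UndefinedBeliefError):
            posterior_combine(flat, flat)

    @pytest.mark.parametrize(
        "lik,prior",
        [
            (GaussianBelief(-6.3, 8.0), GaussianBelief(0.0, 11.5)),
            (GaussianBelief(25.0, 3.0), GaussianBelief(-5.0, 20.0)),
            (GaussianBelief(0.0, 15.0), GaussianBelief(2.0, 1.5)),
        ],
    )
    def test_matches_grid_oracle(self, lik, prior):
        """Mean and SD agree with the numerically gridded density product."""
        post = posterior_combine(lik, prior)
        mean, sd = grid_posterior_oracle(lik, prior)
        assert post.mean == pytest.approx(mean, abs=1e-6)
        assert post.sd == pytest.approx(sd, rel=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(m1=finite_means, s1=sds, m2=finite_means, s2=sds)
    def test_precision_additivity_and_shrinkage(self, m1, s1, m2, s2):
        """1/sd_post^2 = 1/sd_lik^2 + 1/sd_prior^2 and sd_post < both widths."""
        post = posterior_combine(GaussianBelief(m1, s1), GaussianBelief(m2, s2))
        assert 1 / post.sd**2 == pytest.approx(1 / s1**2 + 1 / s2**2, rel=1e-12)
        assert post.sd < min(s1, s2)
        assert min(m1, m2) - 1e-9 <= post.mean <= max(m1, m2) + 1e-9


class TestGainCurves:
    def test_map_gain_printed_example(self):
        assert round(map_gain(8.0, 11.5), 2) == 0.67

    def test_map_gain_limits(self):
        assert map_gain(0.0, 11.5) == 1.0
        assert map_gain(7.0, 7.0) == pytest.approx(0.5)
        assert map_gain(123.0, math.inf) == 1.0  # MLE as the flat-prior limit

    @settings(derandomize=True, max_examples=100)
    @given(sig=st.floats(0.1, 100), sig2=st.floats(0.1, 100), sp=st.floats(1, 50))
    def test_map_gain_monotone_in_noise(self, sig, sig2, sp):
        lo, hi = sorted([sig, sig2])
        assert map_gain(hi, sp) <= map_gain(lo, sp)
        assert 0 < map_gain(hi, sp) <= 1

    def test_map_gain_domain_error(self):
        with pytest.raises(ValueError):
            map_gain(8.0, 0.0)
        with pytest.raises(ValueError):
            map_gain(-1.0, 11.5)

    def test_map_sigma_curve(self):
        assert map_sigma_curve(0.5, 11.5) == pytest.approx(5.75)
        assert map_sigma_curve(0.0, 11.5) == 0.0
        assert map_sigma_curve(1.0, 11.5) == 0.0
        g = map_gain(8.0, 11.5)
        assert round(map_sigma_curve(g, 11.5), 1) == 5.4
        with pytest.raises(ValueError):
            map_sigma_curve(1.2, 11.5)

    def test_map_sigma_equals_gain_times_noise(self):
        """Eliminating sigma_T between the gain and SD expressions recovers the parabola."""
        sigma_T = np.linspace(0.1, 80, 200)
        g = map_gain(sigma_T, 11.5)
        np.testing.assert_allclose(map_sigma_curve(g, 11.5), g * sigma_T, rtol=1e-10)
        np.testing.assert_allclose(map_response_sd(sigma_T, 11.5), g * sigma_T, rtol=1e-12)

    def test_sigma_ordering(self):
        """sigma_MAP < sigma_POST < min(sigma_T, sigma_P) for 0 < G < 1."""
        for sigma_T in (2.0, 8.0, 30.0):
            s_map = map_response_sd(sigma_T, 11.5)
            s_post = posterior_sd(sigma_T, 11.5)
            assert s_map < s_post < min(sigma_T, 11.5)

    def test_as_and_pm_curves(self):
        assert as_gain_curve(11.5, 11.5) == pytest.approx(0.0)
        assert as_gain_curve(0.0, 11.5) == 1.0
        assert as_gain_curve(11.5 / math.sqrt(2), 11.5) == pytest.approx(0.5)
        assert pm_gain_curve(11.5, 11.5) == pytest.approx(0.0)
        assert pm_gain_curve(0.0, 11.5) == 1.0
        with pytest.raises(ValueError):
            as_gain_curve(12.0, 11.5)
        with pytest.raises(ValueError):
            pm_gain_curve(12.0, 11.5)

    @settings(derandomize=True, max_examples=100)
    @given(sigma=st.floats(0, 1), sp=st.floats(1, 50))
    def test_pm_curve_is_exact_identity(self, sigma, sp):
        """sigma_PM^2 = (1 - G^2) sigma_P^2 inverts pm_gain_curve exactly."""
        s = sigma * sp
        g = pm_gain_curve(s, sp)
        assert (1 - g**2) * sp**2 == pytest.approx(s**2, abs=1e-9 * sp**2)


class TestTypes:
    def test_belief_validation(self):
        with pytest.raises(ValueError):
            GaussianBelief(0.0, 0.0)
        with pytest.raises(ValueError):
            GaussianBelief(math.nan, 5.0)
        assert GaussianBelief(0.0, math.inf).is_flat

    def test_spatial_prior_ordering(self):
        SpatialPrior(GaussianBelief(0.0, math.inf), GaussianBelief(0.0, 11.5))
        with pytest.raises(ValueError):
            SpatialPrior(GaussianBelief(0.0, 5.0), GaussianBelief(0.0, 11.5))
        with pytest.raises(ValueError):
            SpatialPrior(GaussianBelief(1.0, 30.0), GaussianBelief(0.0, 11.5))

    def test_noise_model_validation(self):
        assert NoiseModel(0.0).sigma_T == 0.0
        with pytest.raises(ValueError):
            NoiseModel(-1.0)
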