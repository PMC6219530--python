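"""Trial-level response selection rules.

Four decision schemes operate on the same trial posterior:

* ``MLE`` — respond at the likelihood peak (flat-prior limit),
* ``MAP`` — respond at the posterior mode (= mean for Gaussians),
* ``PM`` (posterior matching) — respond with one random draw from the full
  posterior,
* ``AS`` (adaptive sampling) — respond with a random draw restricted to a
  window ``[mu_POST - h, mu_POST + h]`` whose half-width ``h = w0 *
  sigma_hat`` scales with the system's estimate of its own sensory noise,
  ``sigma_hat^2 = sigma_POST^2 / (1 - sigma_POST^2 / sigma_P^2)``.
  Algebraically ``sigma_hat = sigma_T``, so the window shrinks to the MAP
  point when the evidence is good and opens onto the whole posterior when
  it is not.

A fifth variant, ``MAP_BOX``, replaces the Gaussian prior with a uniform
box: its MAP estimate is simply the likelihood peak clipped to the box.

All stochastic operations take an explicit ``numpy.random.Generator``; there
is no global random state. Scalar per-trial functions and the vectorised
block kernel (:func:`apply_scheme`) share one code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bayes_core import GaussianBelief, NoiseModel, map_gain, posterior_combine

__all__ = [
    "SCHEMES",
    "DecisionConfig",
    "sample_likelihood_peak",
    "decide_mle",
    "decide_map",
    "decide_pm",
    "estimate_sampling_halfwidth",
    "decide_as",
    "decide_map_box",
    "apply_scheme",
    "posterior_for_trial",
]

SCHEMES = ("MLE", "MAP", "PM", "AS", "MAP_BOX")

#: relative tolerance below the prior width at which the AS window is
#: declared divergent and sampling falls back to the full posterior
_DIVERGENCE_RTOL = 1e-6


@dataclass(frozen=True)
class DecisionConfig:
    """Configuration of a response decision rule.

    Parameters
    ----------
    scheme : str
        One of ``MLE, MAP, PM, AS, MAP_BOX``.
    w0 : float
        Dimensionless sampling-width factor of the AS rule (default 0.9).
    box_halfwidth : float
        Half-width in degrees of the uniform box prior (MAP_BOX only).
    as_law : str
        Within-window sampling law for AS: ``"truncated"`` (posterior
        truncated to the window; default) or ``"uniform"``.
    rng_seed : int or None
        Seed for the scheme's own generator when no generator is passed in.
    """

    scheme: str = "MAP"
    w0: float = 0.9
    box_halfwidth: float = 35.0
    as_law: str = "truncated"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if not self.w0 > 0:
            raise ValueError(f"w0 must be > 0, got {self.w0}")
        if self.as_law not in ("truncated", "uniform"):
            raise ValueError(f"as_law must be 'truncated' or 'uniform', got {self.as_law!r}")
        if not self.box_halfwidth > 0:
            raise ValueError(f"box_halfwidth must be > 0, got {self.box_halfwidth}")


def sample_likelihood_peak(target, noise: NoiseModel, rng: np.random.Generator, size=None):
    """Draw the trial's noisy internal estimate ``eps* = target + eta``.

    ``eta ~ N(0, sigma_T^2)``; across many trials eps* scatters around the
    true target with SD ``sigma_T``. With ``sigma_T = 0`` the estimate is
    the target itself.
    """
    target = np.asarray(target, dtype=float)
    shape = target.shape if size is None else (size,)
    if noise.sigma_T == 0:
        out = np.broadcast_to(target, shape)
        return float(out) if out.ndim == 0 else out.copy()
    draws = target + rng.normal(0.0, noise.sigma_T, size=shape)
    return float(draws) if draws.ndim == 0 else draws


def decide_mle(eps_star):
    """Maximum-likelihood response: the likelihood peak itself."""
    return eps_star


def decide_map(posterior: GaussianBelief) -> float:
    """MAP response: the posterior mode, which for a Gaussian is its mean."""
    return posterior.mean


def decide_pm(posterior: GaussianBelief, rng: np.random.Generator) -> float:
    """Posterior-matching response: one draw from the full posterior."""
    if posterior.is_flat:
        raise ValueError("cannot sample a flat posterior")
    if posterior.sd == 0:  # degenerate point mass
        return posterior.mean
    return float(rng.normal(posterior.mean, posterior.sd))


def estimate_sampling_halfwidth(posterior_sd: float, prior_sd: float, w0: float = 0.9) -> float:
    """AS window half-width ``w0 * sigma_hat``.

    ``sigma_hat^2 = sigma_POST^2 / (1 - sigma_POST^2 / sigma_P^2)`` is the
    system's reconstruction of its sensory noise from the two widths it has
    access to; it equals ``sigma_T`` exactly. When the posterior width
    reaches the prior width (no sensory evidence) the estimate diverges and
    ``math.inf`` is returned — callers fall back to full-posterior sampling.
    """
    if not w0 > 0:
        raise ValueError("w0 must be > 0")
    if posterior_sd < 0:
        raise ValueError("posterior_sd must be >= 0")
    if posterior_sd == 0:
        return 0.0
    if math.isinf(prior_sd):
        return w0 * posterior_sd
    if posterior_sd >= prior_sd * (1.0 - _DIVERGENCE_RTOL):
        return math.inf
    sigma_hat_sq = posterior_sd**2 / (1.0 - (posterior_sd / prior_sd) ** 2)
    return w0 * math.sqrt(sigma_hat_sq)


def _truncated_normal(rng, mu, sigma, halfwidth, size=None):
    """Draws from N(mu, sigma^2) truncated to [mu - halfwidth, mu + halfwidth]."""
    c = halfwidth / sigma
    draws = stats.truncnorm.rvs(-c, c, loc=mu, scale=sigma, size=size, random_state=rng)
    return draws


def decide_as(
    posterior: GaussianBelief,
    prior: GaussianBelief,
    config: DecisionConfig,
    rng: np.random.Generator,
) -> float:
    """Adaptive-sampling response: a draw restricted to the AS window.

    The window is centred on the posterior mean with half-width from
    :func:`estimate_sampling_halfwidth`. A divergent window (posterior as
    wide as the prior, i.e. no usable sensory evidence) falls back to a
    full-posterior draw; a zero window returns the MAP point.
    """
    if posterior.sd == 0:
        return posterior.mean
    h = estimate_sampling_halfwidth(posterior.sd, prior.sd, config.w0)
    if h == 0.0:
        return posterior.mean
    if math.isinf(h):
        return decide_pm(posterior, rng)
    if config.as_law == "uniform":
        return float(rng.uniform(posterior.mean - h, posterior.mean + h))
    return float(_truncated_normal(rng, posterior.mean, posterior.sd, h))


def decide_map_box(eps_star, box_halfwidth: float):
    """MAP response under a uniform box prior: the clipped likelihood peak.

    The posterior is the likelihood truncated to the box, whose mode is the
    likelihood peak if interior, else the nearer box edge.
    """
    if not box_halfwidth > 0:
        raise ValueError("box_halfwidth must be > 0")
    out = np.clip(np.asarray(eps_star, dtype=float), -box_halfwidth, box_halfwidth)
    return float(out) if out.ndim == 0 else out


def apply_scheme(
    eps_star: np.ndarray,
    noise: NoiseModel,
    prior: GaussianBelief,
    config: DecisionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised response selection for a block of trials.

    Applies ``config.scheme`` to every internal estimate in ``eps_star``
    given a shared noise level and prior. This is the kernel behind the
    block simulator; the scalar ``decide_*`` functions implement the same
    rules trial by trial.
    """
    eps_star = np.asarray(eps_star, dtype=float)
    n = eps_star.shape[0]
    scheme = config.scheme

    if scheme == "MLE":
        return eps_star.copy()
    if scheme == "MAP_BOX":
        return decide_map_box(eps_star, config.box_halfwidth)

    if noise.sigma_T == 0:  # point-mass posterior at eps_star (= target)
        return eps_star.copy()

    gain = map_gain(noise.sigma_T, prior.sd)
    mu_post = prior.mean + gain * (eps_star - prior.mean)
    sigma_post = math.sqrt(gain) * noise.sigma_T

    if scheme == "MAP":
        return mu_post
    if scheme == "PM":
        return mu_post + rng.normal(0.0, sigma_post, size=n)
    # AS: the half-width is shared across the block (sigma_hat = sigma_T)
    h = estimate_sampling_halfwidth(sigma_post, prior.sd, config.w0)
    if math.isinf(h):
        return mu_post + rng.normal(0.0, sigma_post, size=n)
    if config.as_law == "uniform":
        return mu_post + rng.uniform(-h, h, size=n)
    return mu_post + _truncated_normal(rng, 0.0, sigma_post, h, size=n)


def posterior_for_trial(eps_star: float, noise: NoiseModel, prior: GaussianBelief) -> GaussianBelief:
    """Trial posterior from a likelihood centred on eps* and the prior."""
    if noise.sigma_T == 0:
        # degenerate: certainty at the internal estimate
        return GaussianBelief(mean=float(eps_star), sd=np.finfo(float).tiny)
    return posterior_combine(GaussianBelief(float(eps_star), noise.sigma_T), prior)
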