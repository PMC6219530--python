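"""Gaussian belief algebra and closed-form gain-variance predictions.

A localisation response model in one spatial coordinate (azimuth or
elevation, plain degrees). Three Gaussian ingredients:

* a *likelihood* centred on the trial's noisy internal estimate
  ``eps_star`` with width ``sigma_T`` (the sensory noise SD),
* a zero-mean spatial *prior* with width ``sigma_P``,
* their product, the *posterior*, again Gaussian with

  .. math::

     \\mu_{POST} = \\frac{\\varepsilon^*}{1 + \\sigma_T^2/\\sigma_P^2},
     \\qquad
     \\sigma_{POST}^2 = \\frac{\\sigma_T^2}{1 + \\sigma_T^2/\\sigma_P^2}.

The MAP response gain is ``G = 1 / (1 + sigma_T^2 / sigma_P^2)`` and each
decision rule implies its own relation between regression gain and residual
SD:

* MAP:  ``sigma^2 = G (1 - G) sigma_P^2``
* AS:   ``G = 1 - sigma^2 / sigma_P^2``
* PM:   ``G = sqrt(1 - sigma^2 / sigma_P^2)``

An infinite SD encodes a flat (uniform) belief exactly; combining with it is
the identity, and the MAP gain tends to 1 (the MLE limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaussianBelief",
    "SpatialPrior",
    "NoiseModel",
    "UndefinedBeliefError",
    "posterior_combine",
    "map_gain",
    "map_response_sd",
    "posterior_sd",
    "map_sigma_curve",
    "as_gain_curve",
    "pm_gain_curve",
]


class UndefinedBeliefError(ValueError):
    """Raised when a belief combination carries no information (two flat SDs)."""


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian belief over one spatial coordinate.

    Parameters
    ----------
    mean : float
        Centre of the belief, in degrees. Must be finite.
    sd : float
        Standard deviation in degrees, strictly positive. ``math.inf`` is
        the canonical encoding of a flat/uniform belief.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"belief mean must be finite, got {self.mean}")
        if not self.sd > 0:
            raise ValueError(f"belief sd must be > 0 (inf allowed), got {self.sd}")

    @property
    def is_flat(self) -> bool:
        return math.isinf(self.sd)

    @property
    def precision(self) -> float:
        """Inverse variance; 0 for a flat belief."""
        return 0.0 if self.is_flat else 1.0 / (self.sd * self.sd)


@dataclass(frozen=True)
class SpatialPrior:
    """Separable 2-D spatial prior: wide in azimuth, narrow in elevation.

    Both components are centred on straight ahead (mean 0); the azimuth
    width must be at least the elevation width, reflecting the much weaker
    pull of the prior on the binaural (azimuth) pathway.
    """

    azimuth: GaussianBelief
    elevation: GaussianBelief

    def __post_init__(self) -> None:
        if self.azimuth.mean != 0.0 or self.elevation.mean != 0.0:
            raise ValueError("spatial prior components must have mean 0")
        if self.azimuth.sd < self.elevation.sd:
            raise ValueError(
                "azimuth prior width must be >= elevation prior width "
                f"({self.azimuth.sd} < {self.elevation.sd})"
            )


@dataclass(frozen=True)
class NoiseModel:
    """Additive, stimulus-independent zero-mean Gaussian sensory noise."""

    sigma_T: float

    def __post_init__(self) -> None:
        if not self.sigma_T >= 0:
            raise ValueError(f"sigma_T must be >= 0, got {self.sigma_T}")


def posterior_combine(likelihood: GaussianBelief, prior: GaussianBelief) -> GaussianBelief:
    """Combine a Gaussian likelihood with a Gaussian prior.

    Precision-weighted combination: posterior precision is the sum of the
    two precisions and the posterior mean is the precision-weighted mean.
    A flat partner (infinite SD) is the exact identity.

    Raises
    ------
    UndefinedBeliefError
        If both beliefs are flat.
    """
    if likelihood.is_flat and prior.is_flat:
        raise UndefinedBeliefError("cannot combine two flat beliefs")
    if prior.is_flat:
        return likelihood
    if likelihood.is_flat:
        return prior
    tau = likelihood.precision + prior.precision
    mean = (likelihood.mean * likelihood.precision + prior.mean * prior.precision) / tau
    return GaussianBelief(mean=mean, sd=math.sqrt(1.0 / tau))


def map_gain(sigma_T, sigma_P):
    """MAP response gain ``G = 1 / (1 + sigma_T^2 / sigma_P^2)``.

    ``sigma_P = inf`` gives the MLE limit G = 1 for any noise level.
    Accepts scalars or arrays in ``sigma_T``.
    """
    sigma_T = np.asarray(sigma_T, dtype=float)
    if np.any(sigma_T < 0):
        raise ValueError("sigma_T must be >= 0")
    if not sigma_P > 0:
        raise ValueError(f"sigma_P must be > 0, got {sigma_P}")
    if math.isinf(sigma_P):
        g = np.ones_like(sigma_T)
    else:
        g = 1.0 / (1.0 + (sigma_T / sigma_P) ** 2)
    return float(g) if g.ndim == 0 else g


def map_response_sd(sigma_T, sigma_P):
    """Predicted response SD of the MAP rule, ``sigma_MAP = G * sigma_T``."""
    return map_gain(sigma_T, sigma_P) * np.asarray(sigma_T, dtype=float)


def posterior_sd(sigma_T, sigma_P):
    """Posterior SD, ``sigma_POST = sqrt(G) * sigma_T``."""
    g = map_gain(sigma_T, sigma_P)
    out = np.sqrt(np.asarray(g)) * np.asarray(sigma_T, dtype=float)
    return float(out) if out.ndim == 0 else out


def map_sigma_curve(gain, sigma_P):
    """MAP gain-variance relation: ``sigma = sigma_P * sqrt(G (1 - G))``.

    A parabola in variance space, maximal at G = 0.5 where it equals
    ``sigma_P / 2``; zero at G in {0, 1}.
    """
    gain = np.asarray(gain, dtype=float)
    if np.any((gain < 0) | (gain > 1)):
        raise ValueError("gain must lie in [0, 1]")
    if not sigma_P > 0 or math.isinf(sigma_P):
        raise ValueError(f"sigma_P must be finite and > 0, got {sigma_P}")
    out = sigma_P * np.sqrt(gain * (1.0 - gain))
    return float(out) if out.ndim == 0 else out


def _check_curve_args(sigma, sigma_P):
    sigma = np.asarray(sigma, dtype=float)
    if not sigma_P > 0 or math.isinf(sigma_P):
        raise ValueError(f"sigma_P must be finite and > 0, got {sigma_P}")
    if np.any(sigma < 0) or np.any(sigma > sigma_P):
        raise ValueError("response SD must lie in [0, sigma_P]; negative gain not modelled")
    return sigma


def as_gain_curve(sigma_AS, sigma_P):
    """Adaptive-sampling gain-variance relation: ``G = 1 - sigma^2 / sigma_P^2``.

    Linear in variance with slope ``-1/sigma_P^2``; crosses G = 0 exactly at
    ``sigma = sigma_P``.
    """
    sigma = _check_curve_args(sigma_AS, sigma_P)
    out = 1.0 - (sigma / sigma_P) ** 2
    return float(out) if out.ndim == 0 else out


def pm_gain_curve(sigma_PM, sigma_P):
    """Posterior-matching gain-variance relation: ``G = sqrt(1 - sigma^2/sigma_P^2)``.

    Equivalent to the exact identity ``sigma^2 = (1 - G^2) sigma_P^2`` that
    holds when each response is a full draw from the trial posterior.
    """
    sigma = _check_curve_args(sigma_PM, sigma_P)
    out = np.sqrt(1.0 - (sigma / sigma_P) ** 2)
    return float(out) if out.ndim == 0 else out
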