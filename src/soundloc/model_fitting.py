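"""Fit the prior width of each decision model to gain-variance data.

Every decision rule predicts its own curve through the (gain, sigma_res)
plane, and all three curves share one free parameter — the prior width
sigma_P. In variance space each model is linear in sigma_P^2:

    predicted sigma^2 = c(G) * sigma_P^2,  with
    c(G) = G (1 - G)   (MAP)
    c(G) = 1 - G       (AS)
    c(G) = 1 - G^2     (PM)

so the least-squares estimate has the closed form
``sigma_P^2 = sum(c_i * s_i^2) / sum(c_i^2)``. Model fit is summarised by
r^2 between observed and predicted residual SDs (on the sigma scale, i.e.
the axes of a gain-vs-SD plot) and models are compared through the Fisher
r-to-z transform of their observed-vs-predicted correlations. The MLE has
no curve at all: it predicts a constant gain independent of sigma_res,
summarised by the gains' mean and SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GainVariancePoint",
    "PriorFit",
    "UnfittableError",
    "variance_factor",
    "fit_prior_width",
    "mle_constant_gain",
    "compare_model_correlations",
    "points_from_frame",
]

_FITTED_SCHEMES = ("MAP", "AS", "PM")


class UnfittableError(ValueError):
    """All variance factors vanish (every gain at a degenerate value)."""


@dataclass(frozen=True)
class GainVariancePoint:
    """One (gain, residual SD) observation per subject x condition x component."""

    subject: str
    condition: str
    component: str
    gain: float
    sigma_res: float

    def __post_init__(self) -> None:
        if self.sigma_res < 0:
            raise ValueError("sigma_res must be >= 0")


@dataclass(frozen=True)
class PriorFit:
    """Fitted prior width and fit quality for one decision-rule model."""

    scheme: str
    sigma_P: float  # nan for MLE (no curve)
    r2: float
    r: float
    n: int


def variance_factor(scheme: str, gains):
    """Model-specific factor c(G) relating gain to predicted variance."""
    g = np.asarray(gains, dtype=float)
    if scheme == "MAP":
        return g * (1.0 - g)
    if scheme == "AS":
        return 1.0 - g
    if scheme == "PM":
        return 1.0 - g**2
    raise ValueError(f"no gain-variance curve for scheme {scheme!r}")


def fit_prior_width(
    points: list[GainVariancePoint], scheme: str, space: str = "variance"
) -> PriorFit:
    """Least-squares fit of sigma_P for one decision-rule model.

    Parameters
    ----------
    points : list of GainVariancePoint
        At least two observations with gains in [0, 1].
    scheme : str
        ``"MAP"``, ``"AS"`` or ``"PM"``.
    space : str
        ``"variance"`` (default): minimise squared error of sigma^2 against
        c(G) sigma_P^2 — closed form ``sigma_P^2 = sum(c s^2)/sum(c^2)``.
        ``"sd"``: minimise squared error on the sigma scale instead
        (``sigma_P = sum(sqrt(c) s)/sum(c)``), a sensitivity check.

    r^2 and r are computed between observed and model-predicted sigma_res
    (the sigma scale in both cases).
    """
    if scheme not in _FITTED_SCHEMES:
        raise ValueError(f"scheme must be one of {_FITTED_SCHEMES}, got {scheme!r}")
    if len(points) < 2:
        raise ValueError("need at least 2 points to fit a prior width")
    gains = np.array([p.gain for p in points], dtype=float)
    sig = np.array([p.sigma_res for p in points], dtype=float)
    if np.any((gains < 0) | (gains > 1)):
        raise ValueError("gains must lie in [0, 1]")
    c = variance_factor(scheme, gains)
    if np.all(c == 0):
        raise UnfittableError(f"all gains degenerate for the {scheme} curve")
    if space == "variance":
        sigma_P_sq = float(np.sum(c * sig**2) / np.sum(c**2))
        sigma_P = math.sqrt(max(sigma_P_sq, 0.0))
    elif space == "sd":
        sigma_P = float(np.sum(np.sqrt(c) * sig) / np.sum(c))
    else:
        raise ValueError(f"space must be 'variance' or 'sd', got {space!r}")
    predicted = np.sqrt(c) * sigma_P
    ss_res = float(np.sum((sig - predicted) ** 2))
    ss_tot = float(np.sum((sig - sig.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    if np.ptp(predicted) == 0 or np.ptp(sig) == 0:
        r = 1.0 if ss_res == 0 else 0.0
    else:
        r = float(np.corrcoef(sig, predicted)[0, 1])
    return PriorFit(scheme=scheme, sigma_P=sigma_P, r2=r2, r=r, n=len(points))


def mle_constant_gain(points: list[GainVariancePoint]) -> tuple[float, float]:
    """MLE prediction: a constant gain. Returns (mean, sample SD) of the gains."""
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    gains = np.array([p.gain for p in points], dtype=float)
    return float(gains.mean()), float(gains.std(ddof=1))


def compare_model_correlations(
    r1: float,
    r2: float,
    n: int,
    method: str = "fisher",
    r12: float | None = None,
    n2: int | None = None,
) -> tuple[float, float]:
    """Compare two correlation coefficients; returns (z, two-sided p).

    ``method="fisher"`` treats the correlations as independent samples:
    ``z = (atanh r1 - atanh r2) / sqrt(1/(n-3) + 1/(n2-3))``.
    ``method="steiger"`` accounts for the correlations sharing one variable
    (here: the observed sigma_res correlated with two model predictions) and
    requires ``r12``, the correlation between the two predictions.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    if method == "fisher":
        m = n if n2 is None else n2
        if m < 4:
            raise ValueError("need n2 >= 4")
        z = (z1 - z2) / math.sqrt(1.0 / (n - 3) + 1.0 / (m - 3))
    elif method == "steiger":
        if r12 is None or not abs(r12) < 1:
            raise ValueError("steiger comparison requires |r12| < 1")
        rm_sq = (r1**2 + r2**2) / 2.0
        f = min((1.0 - r12) / (2.0 * (1.0 - rm_sq)), 1.0)
        h = (1.0 - f * rm_sq) / (1.0 - rm_sq)
        z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    else:
        raise ValueError(f"method must be 'fisher' or 'steiger', got {method!r}")
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def points_from_frame(summary: pd.DataFrame, component: str | None = None) -> list[GainVariancePoint]:
    """Build gain-variance points from a regression-summary table.

    Expects columns ``subject, condition, component, gain, sigma_res``;
    rows flagged ``excluded`` (if the column is present) are dropped, as is
    any other component when ``component`` is given.
    """
    df = summary
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    if component is not None:
        df = df[df["component"] == component]
    return [
        GainVariancePoint(
            subject=str(row.subject),
            condition=str(row.condition),
            component=str(row.component),
            gain=float(np.clip(row.gain, 0.0, 1.0)),
            sigma_res=float(row.sigma_res),
        )
        for row in df.itertuples(index=False)
    ]
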