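"""Stimulus-response regression and the group-level gain exclusion rule.

The accuracy of a localisation data set is summarised by the least-squares
line ``R = g * T + b`` (gain g, bias b) and its precision by the residual
SD ``sigma_res = sqrt(mean((R - R_pred)^2))`` — a plain mean over trials,
matching the definition used throughout this analysis (at n = 1000 the
difference from the n-2 divisor is ~0.1%). Biases are reported but never
propagated into the gain-variance analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RegressionResult", "fit_linear", "exclude_outlier_gains", "regress_study"]


@dataclass(frozen=True)
class RegressionResult:
    """Least-squares summary of one stimulus-response set."""

    gain: float
    bias: float
    sigma_res: float
    n: int


def fit_linear(targets, responses) -> RegressionResult:
    """Least-squares regression of responses on targets.

    Minimises the mean squared error of ``g * T + b``; ``sigma_res`` is the
    root mean squared residual (population divisor n).

    Raises
    ------
    ValueError
        On length mismatch, fewer than two points, or all-identical targets
        (rank-deficient design).
    """
    t = np.asarray(targets, dtype=float)
    r = np.asarray(responses, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("targets and responses must be 1-D arrays of equal length")
    n = t.size
    if n < 2:
        raise ValueError("need at least 2 trials for a regression")
    if np.ptp(t) == 0:
        raise ValueError("targets are all identical; regression is rank-deficient")
    # closed-form normal equations for the simple linear model
    t_mean = t.mean()
    r_mean = r.mean()
    gain = float(np.sum((t - t_mean) * (r - r_mean)) / np.sum((t - t_mean) ** 2))
    bias = float(r_mean - gain * t_mean)
    resid = r - (gain * t + bias)
    sigma_res = float(np.sqrt(np.mean(resid**2)))
    return RegressionResult(gain=gain, bias=bias, sigma_res=sigma_res, n=n)


def exclude_outlier_gains(
    results: list[RegressionResult], n_sd: float = 3.0
) -> tuple[list[RegressionResult], list[RegressionResult]]:
    """Single-pass exclusion of regression gains more than ``n_sd`` SDs from the mean.

    Mean and (sample, ddof=1) SD are computed over the full input set; any
    result whose gain deviates by more than ``n_sd`` standard deviations is
    moved to the excluded list. With fewer than 3 results the rule is a
    no-op (a warning is emitted and everything is kept). Identical gains
    (SD = 0) exclude nothing.
    """
    if len(results) < 3:
        warnings.warn("fewer than 3 regression results; outlier exclusion skipped")
        return list(results), []
    gains = np.array([res.gain for res in results], dtype=float)
    mean = gains.mean()
    sd = gains.std(ddof=1)
    if sd == 0:
        return list(results), []
    outlier = np.abs(gains - mean) > n_sd * sd
    kept = [res for res, bad in zip(results, outlier) if not bad]
    excluded = [res for res, bad in zip(results, outlier) if bad]
    return kept, excluded


def regress_study(trials, n_sd: float = 3.0):
    """Per subject x condition x component regression over a study trial table.

    ``trials`` must carry columns ``experiment, subject, condition,
    target_az, target_el, resp_az, resp_el``. Each (subject, condition)
    cell is regressed separately for azimuth and elevation, then the 3-SD
    gain-exclusion rule is applied pooled within experiment x component.

    Returns a DataFrame with columns ``experiment, subject, condition,
    component, gain, bias, sigma_res, n, excluded``.
    """
    import pandas as pd  # local import: keep the numeric core pandas-free

    rows = []
    for (experiment, subject, condition), cell in trials.groupby(
        ["experiment", "subject", "condition"], sort=False
    ):
        for component in ("azimuth", "elevation"):
            suffix = "az" if component == "azimuth" else "el"
            fit = fit_linear(cell[f"target_{suffix}"], cell[f"resp_{suffix}"])
            rows.append(
                {
                    "experiment": experiment,
                    "subject": subject,
                    "condition": condition,
                    "component": component,
                    "gain": fit.gain,
                    "bias": fit.bias,
                    "sigma_res": fit.sigma_res,
                    "n": fit.n,
                }
            )
    summary = pd.DataFrame(rows)
    summary["excluded"] = False
    for (_, _), group in summary.groupby(["experiment", "component"], sort=False):
        if len(group) < 3:
            continue
        gains = group["gain"].to_numpy()
        sd = gains.std(ddof=1)
        if sd == 0:
            continue
        bad = np.abs(gains - gains.mean()) > n_sd * sd
        summary.loc[group.index[bad], "excluded"] = True
    return summary
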