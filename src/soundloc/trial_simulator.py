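"""Monte-Carlo trial ensembles and the gain-variance noise sweep.

:func:`simulate_block` draws a block of trials with uniformly distributed
targets, adds Gaussian sensory noise, and applies one decision rule;
:func:`noise_sweep` repeats that over a grid of noise levels and schemes and
reduces each block to a regression (gain, residual SD) pair — one point of
the gain-variance plane per scheme and noise condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayes_core import GaussianBelief, NoiseModel
from .decision_rules import DecisionConfig, apply_scheme, sample_likelihood_peak
from .response_regression import fit_linear

__all__ = [
    "SimulationConfig",
    "TrialRecord",
    "simulate_block",
    "noise_sweep",
    "default_sigma_grid",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated block: uniform targets, one noise level, one rule."""

    target_low: float = -35.0
    target_high: float = 35.0
    n_trials: int = 1000
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(8.0))
    prior: GaussianBelief = field(default_factory=lambda: GaussianBelief(0.0, 11.5))
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_low < self.target_high:
            raise ValueError("target_low must be < target_high")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial: true target, internal estimate, response."""

    index: int
    target: float
    eps_star: float
    response: float


def simulate_block(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one block of trials under a single decision rule.

    Targets are continuous-uniform on ``[target_low, target_high]``; each
    trial's internal estimate is the target plus Gaussian sensory noise and
    the response follows the configured decision scheme.

    Returns a DataFrame with columns ``trial, target, eps_star, response``
    (one row per trial, bitwise reproducible for a given config and seed).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    targets = rng.uniform(config.target_low, config.target_high, size=config.n_trials)
    eps_star = sample_likelihood_peak(targets, config.noise, rng, size=None)
    responses = apply_scheme(eps_star, config.noise, config.prior, config.decision, rng)
    return pd.DataFrame(
        {
            "trial": np.arange(config.n_trials),
            "target": targets,
            "eps_star": np.asarray(eps_star, dtype=float),
            "response": responses,
        }
    )


def records(block: pd.DataFrame) -> list[TrialRecord]:
    """View a simulated block as a list of :class:`TrialRecord`."""
    return [
        TrialRecord(int(r.trial), float(r.target), float(r.eps_star), float(r.response))
        for r in block.itertuples(index=False)
    ]


def default_sigma_grid() -> np.ndarray:
    """Noise grid sigma_T = 1, 1.5, ..., 60 deg (119 conditions)."""
    return np.arange(1.0, 60.0 + 1e-9, 0.5)


def noise_sweep(
    sigma_grid=None,
    schemes=("MAP", "PM", "AS"),
    n_per_condition: int = 1000,
    target_range: tuple[float, float] = (-90.0, 90.0),
    prior: GaussianBelief | None = None,
    w0: float = 0.9,
    seed: int = 0,
    as_law: str = "truncated",
) -> pd.DataFrame:
    """Sweep sensory noise levels and reduce each block to (gain, sigma_res).

    For every scheme and every ``sigma_T`` on the grid, simulates a block of
    ``n_per_condition`` trials with uniform targets and fits the
    stimulus-response regression. Each (scheme, sigma_T) condition gets an
    independent child seed so rows are reproducible individually.

    Returns a DataFrame with columns ``scheme, sigma_T, gain, sigma_res, n``.
    """
    if sigma_grid is None:
        sigma_grid = default_sigma_grid()
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_grid.size == 0:
        raise ValueError("sigma_grid must be nonempty")
    if n_per_condition < 2:
        raise ValueError("n_per_condition must be >= 2")
    if prior is None:
        prior = GaussianBelief(0.0, 11.5)

    seeds = np.random.SeedSequence(seed).spawn(len(schemes) * sigma_grid.size)
    rows = []
    k = 0
    for scheme in schemes:
        decision = DecisionConfig(scheme=scheme, w0=w0, as_law=as_law)
        for sigma_T in sigma_grid:
            config = SimulationConfig(
                target_low=target_range[0],
                target_high=target_range[1],
                n_trials=n_per_condition,
                noise=NoiseModel(float(sigma_T)),
                prior=prior,
                decision=decision,
            )
            block = simulate_block(config, rng=np.random.default_rng(seeds[k]))
            k += 1
            fit = fit_linear(block["target"].to_numpy(), block["response"].to_numpy())
            rows.append(
                {
                    "scheme": scheme,
                    "sigma_T": float(sigma_T),
                    "gain": fit.gain,
                    "sigma_res": fit.sigma_res,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)
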