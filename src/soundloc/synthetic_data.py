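"""Synthetic study-shaped localisation data sets.

The behavioural data behind this analysis (eye saccades to buzzers embedded
in acoustic background noise at several SNRs; head saccades to low-pass
filtered noises) are not publicly deposited, so this module generates trial
tables with the same shape and the statistical structure the analysis
assumes:

* **SNR experiment** — 5 subjects, SNRs +30, -6, -12, -18, -21 dB, targets
  on a polar grid of 12 directions x eccentricities {14, 20, 27} deg inside
  the +/-35 deg oculomotor range. Elevation responses follow the
  adaptive-sampling rule with a narrow prior (sigma_P ~ 11.5 deg) and a
  sensory noise level that grows as SNR drops; azimuth responses are
  MLE-like with a constant motor gain of ~0.9.
* **Low-pass experiment** — 7 subjects, targets over the frontal hemifield
  in double-pole coordinates (|azimuth| + |elevation| <= 90 deg). Low-pass
  sounds carry no spectral elevation cues, so elevation responses are pure
  prior draws (sensory noise = infinity); azimuth responses remain
  high-gain.

The SNR -> sigma_T map is a logistic in dB — a fixture choice, not a claim
about auditory physiology; the study this emulates reports gains and
variabilities per SNR but no explicit noise law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_core import GaussianBelief, NoiseModel
from .decision_rules import DecisionConfig, apply_scheme

__all__ = [
    "SnrNoiseMap",
    "SyntheticStudyConfig",
    "snr_to_sigma",
    "snr_target_grid",
    "lowpass_targets",
    "generate_snr_experiment",
    "generate_lowpass_experiment",
    "generate_study",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "experiment",
    "subject",
    "condition",
    "trial",
    "target_az",
    "target_el",
    "resp_az",
    "resp_el",
]


@dataclass(frozen=True)
class SnrNoiseMap:
    """Logistic SNR -> sensory-noise map (monotone decreasing in SNR).

    ``sigma(snr) = sigma_min + (sigma_max - sigma_min) / (1 + exp((snr - midpoint)/slope))``

    Defaults span elevation MAP gains from ~0.87 at +30 dB down to ~0.32 at
    -21 dB for a prior width of 11.5 deg.
    """

    sigma_min: float = 4.5
    sigma_max: float = 20.0
    midpoint_db: float = -14.0
    slope_db: float = 5.0

    def __post_init__(self) -> None:
        if not (self.sigma_min >= 0 and self.sigma_max > self.sigma_min):
            raise ValueError("need 0 <= sigma_min < sigma_max")
        if not self.slope_db > 0:
            raise ValueError("slope_db must be > 0 (monotone decreasing map)")


def snr_to_sigma(snr_db, params: SnrNoiseMap | None = None):
    """Sensory noise SD (deg) for a given SNR (dB); vectorised."""
    p = params if params is not None else SnrNoiseMap()
    snr = np.asarray(snr_db, dtype=float)
    out = p.sigma_min + (p.sigma_max - p.sigma_min) / (1.0 + np.exp((snr - p.midpoint_db) / p.slope_db))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Configuration of a synthetic localisation study.

    ``trials_per_condition=None`` uses the study counts: 72 trials in the
    +30 dB (no-background) condition, 24 otherwise, and ~100 per subject in
    the low-pass experiment. Subject heterogeneity is mild lognormal-free
    Gaussian jitter on the prior width (SD ``sigma_P_jitter``) and on the
    noise-map midpoint (SD ``midpoint_jitter_db``).
    """

    experiment: str = "SNR"
    n_subjects: int | None = None  # defaults: 5 for SNR, 7 for LOWPASS
    snr_levels: tuple[float, ...] = (30.0, -6.0, -12.0, -18.0, -21.0)
    trials_per_condition: int | None = None
    sigma_P_el: float = 11.5
    sigma_P_jitter: float = 1.0
    midpoint_jitter_db: float = 2.0
    azimuth_motor_gain: float = 0.9
    azimuth_noise: SnrNoiseMap = field(
        default_factory=lambda: SnrNoiseMap(sigma_min=2.5, sigma_max=6.0, midpoint_db=-16.0, slope_db=5.0)
    )
    elevation_noise: SnrNoiseMap = field(default_factory=SnrNoiseMap)
    elevation_scheme: DecisionConfig = field(default_factory=lambda: DecisionConfig(scheme="AS"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("SNR", "LOWPASS"):
            raise ValueError("experiment must be 'SNR' or 'LOWPASS'")
        if self.n_subjects is not None and self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def subjects(self) -> int:
        if self.n_subjects is not None:
            return self.n_subjects
        return 5 if self.experiment == "SNR" else 7


def snr_target_grid() -> np.ndarray:
    """Polar target grid: 12 directions x eccentricities {14, 20, 27} deg.

    Returns an (36, 2) array of (azimuth, elevation) pairs, all inside the
    +/-35 deg response range.
    """
    directions = np.deg2rad(np.arange(12) * 30.0)
    eccentricities = np.array([14.0, 20.0, 27.0])
    az = np.outer(eccentricities, np.cos(directions)).ravel()
    el = np.outer(eccentricities, np.sin(directions)).ravel()
    return np.column_stack([az, el])


def lowpass_targets(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform targets over the frontal hemifield in double-pole coordinates.

    Rejection-samples azimuth in [-90, +90] and elevation in [-55, +85]
    subject to |azimuth| + |elevation| <= 90 deg.
    """
    out = np.empty((0, 2))
    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]), 16)
        az = rng.uniform(-90.0, 90.0, size=m)
        el = rng.uniform(-55.0, 85.0, size=m)
        ok = np.abs(az) + np.abs(el) <= 90.0
        out = np.vstack([out, np.column_stack([az[ok], el[ok]])])
    return out[:n]


def _subject_params(config: SyntheticStudyConfig, rng: np.random.Generator):
    """Per-subject prior width and noise-map midpoint jitter."""
    sigma_P = max(config.sigma_P_el + rng.normal(0.0, config.sigma_P_jitter), 2.0)
    d_mid = rng.normal(0.0, config.midpoint_jitter_db)
    return sigma_P, d_mid


def _azimuth_response(targets_az, sigma_az, gain, rng):
    """MLE-like azimuth response scaled by a constant motor gain."""
    return gain * (targets_az + rng.normal(0.0, sigma_az, size=targets_az.shape))


def generate_snr_experiment(config: SyntheticStudyConfig | None = None) -> pd.DataFrame:
    """Generate the synthetic SNR experiment trial table.

    One row per subject x SNR x trial, with targets cycled through the
    polar grid, elevation responses from the configured decision rule
    (default AS) and azimuth responses MLE-like at constant motor gain.
    """
    config = config if config is not None else SyntheticStudyConfig(experiment="SNR")
    rng = np.random.default_rng(config.seed)
    grid = snr_target_grid()
    frames = []
    for s in range(config.subjects):
        subject = f"S{s + 1}"
        sigma_P, d_mid = _subject_params(config, rng)
        prior = GaussianBelief(0.0, sigma_P)
        el_map = SnrNoiseMap(
            sigma_min=config.elevation_noise.sigma_min,
            sigma_max=config.elevation_noise.sigma_max,
            midpoint_db=config.elevation_noise.midpoint_db + d_mid,
            slope_db=config.elevation_noise.slope_db,
        )
        for snr in config.snr_levels:
            if config.trials_per_condition is not None:
                n = config.trials_per_condition
            else:
                n = 72 if snr >= 0 else 24
            if n == 0:
                continue
            # cycle the grid so every condition covers the speaker layout
            idx = np.concatenate(
                [rng.permutation(grid.shape[0]) for _ in range(math.ceil(n / grid.shape[0]))]
            )[:n]
            targets = grid[idx]
            sigma_el = snr_to_sigma(snr, el_map)
            sigma_az = snr_to_sigma(snr, config.azimuth_noise)
            eps_star_el = targets[:, 1] + rng.normal(0.0, sigma_el, size=n)
            resp_el = apply_scheme(
                eps_star_el, NoiseModel(sigma_el), prior, config.elevation_scheme, rng
            )
            resp_az = _azimuth_response(targets[:, 0], sigma_az, config.azimuth_motor_gain, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "experiment": "SNR",
                        "subject": subject,
                        "condition": f"{snr:+g}dB",
                        "trial": np.arange(n),
                        "target_az": targets[:, 0],
                        "target_el": targets[:, 1],
                        "resp_az": resp_az,
                        "resp_el": resp_el,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def generate_lowpass_experiment(config: SyntheticStudyConfig | None = None) -> pd.DataFrame:
    """Generate the synthetic low-pass experiment trial table.

    Elevation carries no sensory information (no spectral cues), so the
    posterior equals the prior and every sampling rule draws from it:
    elevation responses are N(0, sigma_P^2) draws regardless of the target.
    Azimuth responses stay high-gain.
    """
    config = config if config is not None else SyntheticStudyConfig(experiment="LOWPASS")
    rng = np.random.default_rng(config.seed)
    n = config.trials_per_condition if config.trials_per_condition is not None else 100
    frames = []
    for s in range(config.subjects):
        subject = f"S{s + 6}"
        sigma_P, _ = _subject_params(config, rng)
        if n == 0:
            continue
        targets = lowpass_targets(n, rng)
        resp_el = rng.normal(0.0, sigma_P, size=n)  # prior-only sampling
        resp_az = _azimuth_response(
            targets[:, 0], config.azimuth_noise.sigma_min, config.azimuth_motor_gain, rng
        )
        frames.append(
            pd.DataFrame(
                {
                    "experiment": "LOWPASS",
                    "subject": subject,
                    "condition": "lowpass",
                    "trial": np.arange(n),
                    "target_az": targets[:, 0],
                    "target_el": targets[:, 1],
                    "resp_az": resp_az,
                    "resp_el": resp_el,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def generate_study(config: SyntheticStudyConfig) -> pd.DataFrame:
    """Dispatch on ``config.experiment``."""
    if config.experiment == "SNR":
        return generate_snr_experiment(config)
    return generate_lowpass_experiment(config)
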