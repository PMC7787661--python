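"""Synthetic generators with known ground truth for the neural pipeline.

The generative model mirrors the structure the preparatory-variability
analyses assume: a low-dimensional latent preparatory state z per trial,
observed through a tall loading matrix on many noisy channels, with the
movement duration linearly coupled to z plus additive execution noise:

    z      ~ Normal(mu_c, (scale_c)^2 I_d)          (condition c)
    rates  = max(0, baseline + L z + obs_noise)
    MD     = md_baseline_c + beta_c . z + eps,  eps ~ Normal(0, sigma_eps^2)

The *true* proportion of MD variance attributable to the preparatory state
is then Var(beta.z) / (Var(beta.z) + sigma_eps^2), available in closed form
— which is what makes parameter-recovery tests possible.

``generate_condition_pair`` builds a two-condition dataset whose MD moments match
the published monkey values (461 +/- 234 ms large, 661 +/- 258 ms small),
with the small-target condition given a *smaller* latent covariance but a
*larger* true explained fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .neural import NeuralTrialSet

__all__ = ["NeuralGenConfig", "GroundTruth", "generate_neural_trials",
           "config_for_fraction", "generate_condition_pair", "make_toy_profiles",
           "CONDITION_MD_MOMENTS", "CONDITION_FRACTIONS"]

#: Published per-condition MD mean and SD (s) the paired generator targets.
CONDITION_MD_MOMENTS = {"large": (0.461, 0.234), "small": (0.661, 0.258)}
#: True explained fractions: ~60% for the small target; just under half for
#: the large target (the practiced-task baseline).
CONDITION_FRACTIONS = {"large": 0.45, "small": 0.60}


@dataclass
class NeuralGenConfig:
    """One condition of the latent-state generator."""

    n_channels: int = 192
    latent_dim: int = 3
    loading_gain: float = 60.0  # Hz of population-rate modulation per latent unit
    baseline_range: tuple[float, float] = (12.0, 42.0)
    latent_mean: float = 0.0
    latent_scale: float = 1.0  # SD multiplier on the identity latent covariance
    coupling: np.ndarray | None = None  # beta, s per latent unit; default 0.2/sqrt(d)
    md_baseline: float = 0.5
    noise_sd: float = 0.16  # execution noise sigma_eps, s
    obs_noise_sd: float = 2.0  # additive Gaussian on rates, Hz
    poisson: bool = False  # Poisson spike counts instead of Gaussian rate noise
    window: float = 0.2  # s; only used by the Poisson observation model
    n_trials: int = 200
    condition: str = "cond"

    def __post_init__(self) -> None:
        if self.coupling is None:
            self.coupling = np.full(self.latent_dim,
                                    0.2 / math.sqrt(self.latent_dim))
        self.coupling = np.asarray(self.coupling, dtype=float)
        if not self.latent_scale > 0:
            raise ValueError("latent covariance scale must be > 0")
        if self.noise_sd < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if len(self.coupling) != self.latent_dim:
            raise ValueError("coupling length must equal latent_dim")

    @property
    def true_fraction(self) -> float:
        """Closed-form Var(beta.z) / (Var(beta.z) + sigma_eps^2)."""
        v = self.latent_scale ** 2 * float(self.coupling @ self.coupling)
        if v == 0 and self.noise_sd == 0:
            return 0.0
        return v / (v + self.noise_sd ** 2)


@dataclass
class GroundTruth:
    latents: np.ndarray  # (n_trials, d)
    explained_fraction: float
    latent_cov: np.ndarray  # (d, d)
    coupling: np.ndarray


def _loadings(cfg: NeuralGenConfig, rng: np.random.Generator) -> np.ndarray:
    G = rng.standard_normal((cfg.n_channels, cfg.latent_dim))
    Q, _ = np.linalg.qr(G)
    return Q * cfg.loading_gain


def generate_neural_trials(cfg: NeuralGenConfig, seed: int = 0,
                           loadings: np.ndarray | None = None,
                           baseline: np.ndarray | None = None):
    """Draw one condition's trial set; returns (NeuralTrialSet, GroundTruth).

    ``loadings``/``baseline`` may be passed in so several conditions share
    the same observation model.  Fully deterministic given (config, seed).
    """
    rng = np.random.default_rng(seed)
    if loadings is None:
        loadings = _loadings(cfg, rng)
    if baseline is None:
        baseline = rng.uniform(*cfg.baseline_range, size=cfg.n_channels)

    n, d = cfg.n_trials, cfg.latent_dim
    z = cfg.latent_mean + cfg.latent_scale * rng.standard_normal((n, d))
    clean = baseline + z @ loadings.T
    if cfg.poisson:
        counts = rng.poisson(np.clip(clean, 0.0, None) * cfg.window)
        rates = counts / cfg.window
    else:
        rates = clean + cfg.obs_noise_sd * rng.standard_normal((n, cfg.n_channels))
    rates = np.clip(rates, 0.0, None)

    md = cfg.md_baseline + z @ cfg.coupling \
        + cfg.noise_sd * rng.standard_normal(n)
    gt = GroundTruth(latents=z, explained_fraction=cfg.true_fraction,
                     latent_cov=cfg.latent_scale ** 2 * np.eye(d),
                     coupling=cfg.coupling.copy())
    ts = NeuralTrialSet(rates=rates, md=md,
                        condition=np.full(n, cfg.condition),
                        ground_truth={"explained_fraction": gt.explained_fraction})
    return ts, gt


def config_for_fraction(fraction: float, base: NeuralGenConfig | None = None,
                        **overrides) -> NeuralGenConfig:
    """Config whose closed-form explained fraction equals ``fraction``.

    Keeps Var(beta.z) from the base config and solves for the execution
    noise: sigma_eps = sqrt(Var(beta.z) (1 - f) / f).  f = 0 zeroes beta.
    """
    base = base or NeuralGenConfig()
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return replace(base, coupling=np.zeros(base.latent_dim), **overrides)
    v = base.latent_scale ** 2 * float(base.coupling @ base.coupling)
    if fraction == 1.0:
        return replace(base, noise_sd=0.0, **overrides)
    noise_sd = math.sqrt(v * (1.0 - fraction) / fraction)
    return replace(base, noise_sd=noise_sd, **overrides)


def _condition_config(label: str, scale: float, n_trials: int) -> NeuralGenConfig:
    mean_md, sd_md = CONDITION_MD_MOMENTS[label]
    f = CONDITION_FRACTIONS[label]
    var_total = sd_md ** 2
    var_plan = f * var_total
    gain = math.sqrt(var_plan) / scale  # |beta| so Var(beta.z) = var_plan
    d = 3
    coupling = np.full(d, gain / math.sqrt(d))
    return NeuralGenConfig(latent_dim=d, latent_scale=scale, coupling=coupling,
                           md_baseline=mean_md,
                           noise_sd=math.sqrt((1.0 - f) * var_total),
                           n_trials=n_trials, condition=label)


def generate_condition_pair(n_trials: int = 200, seed: int = 0,
                       scale_small: float = 0.6, scale_large: float = 1.0):
    """Two-condition synthetic dataset emulating the small/large-target design.

    By construction the small condition has smaller latent covariance
    (scale 0.6 vs 1.0), larger MD mean and SD, and a higher true explained
    fraction; both conditions share one loading matrix and channel baselines.
    Returns (set_small, set_large, {"small": GroundTruth, "large": ...}).
    """
    rng = np.random.default_rng(seed)
    shared = NeuralGenConfig()
    loadings = _loadings(shared, rng)
    baseline = rng.uniform(*shared.baseline_range, size=shared.n_channels)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=2)

    cfg_small = _condition_config("small", scale_small, n_trials)
    cfg_large = _condition_config("large", scale_large, n_trials)
    set_small, gt_small = generate_neural_trials(cfg_small, int(sub_seeds[0]),
                                                 loadings, baseline)
    set_large, gt_large = generate_neural_trials(cfg_large, int(sub_seeds[1]),
                                                 loadings, baseline)
    return set_small, set_large, {"small": gt_small, "large": gt_large}


def make_toy_profiles(kind: str, n: int = 200):
    """Constructed hand-speed profiles for kinematics-analysis tests.

    ``symmetric``: sin^2 bell peaking at t = 0.5.  ``skewed``: beta-shaped
    bell with mode 0.66.  ``two_bump``: bimodal profile with exactly one
    interior local minimum.  Returns (times in [0, 1], speeds).
    """
    if n < 10:
        raise ValueError("need at least 10 points")
    t = np.linspace(0.0, 1.0, n)
    if kind == "symmetric":
        v = np.sin(np.pi * t) ** 2
    elif kind == "skewed":
        mode = 0.66
        a, b = 1.0 + 4.0 * mode, 5.0 - 4.0 * mode  # beta-pdf mode at 0.66
        v = t ** (a - 1.0) * (1.0 - t) ** (b - 1.0)
        v = v / v.max()
    elif kind == "two_bump":
        v = (np.exp(-(((t - 0.30) / 0.12) ** 2))
             + 0.7 * np.exp(-(((t - 0.75) / 0.12) ** 2)))
        v = v / v.max()
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    return t, v
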