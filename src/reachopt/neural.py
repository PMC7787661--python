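"""Preparatory-state variability analyses on trial x channel firing rates.

Given per-trial multi-channel firing rates averaged over a pre-go-cue
preparatory window, plus per-trial movement durations, this module measures:

* across-trial preparatory variability, summarized as the volume of the
  error ellipsoid in the top-3 principal-component space;
* the proportion of MD variance explained by the preparatory state, via
  leave-one-out cross-validated linear regression on top-k PC scores;
* a two-sample F-test comparing MD variances between conditions.

All quantitative validation runs on synthetic trial sets with known ground
truth (see :mod:`reachopt.synthetic`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "NeuralTrialSet", "PrepVariabilityResult", "prep_states", "ellipse_volume",
    "normalized_volumes", "proportion_md_explained", "variance_f_test",
    "preparatory_summary", "planning_md_reduction", "planning_share_of_gap",
    "coefficient_of_variation",
]


@dataclass
class NeuralTrialSet:
    """Trials of one (or more) conditions: window-averaged rates plus MDs."""

    rates: np.ndarray  # (n_trials, n_channels), spikes/s, >= 0
    md: np.ndarray  # (n_trials,), s
    condition: np.ndarray  # (n_trials,) labels, e.g. "small" / "large"
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.md = np.asarray(self.md, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.rates.ndim != 2:
            raise ValueError("rates must be (trials, channels)")
        if not (len(self.md) == len(self.rates) == len(self.condition)):
            raise ValueError("rates, md, and condition must align per trial")
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.rates.shape[1]

    def subset(self, label) -> "NeuralTrialSet":
        m = self.condition == label
        return NeuralTrialSet(self.rates[m], self.md[m], self.condition[m],
                              self.ground_truth)


def prep_states(counts: np.ndarray, bin_width: float, window: float) -> np.ndarray:
    """Window-averaged firing rates from binned spike counts.

    ``counts`` is (trials, channels, bins) over the preparatory epoch; the
    last ``window`` seconds are averaged into one rate per trial and channel.
    """
    counts = np.asarray(counts, dtype=float)
    n_bins = int(round(window / bin_width))
    if n_bins < 1 or n_bins > counts.shape[-1]:
        raise ValueError(
            f"window {window}s needs {n_bins} bins; epoch has {counts.shape[-1]}")
    return counts[..., -n_bins:].sum(axis=-1) / (n_bins * bin_width)


def _pca_sds(states: np.ndarray):
    X = states - states.mean(axis=0)
    n = X.shape[0]
    svals = np.linalg.svd(X, compute_uv=False)
    var = svals ** 2 / (n - 1)
    return np.sqrt(var), var


def ellipse_volume(states: np.ndarray, rank_tol: float = 1e-10):
    """Error-ellipsoid volume in the top-3 PC space, and captured variance.

    Volume = (4/3) pi s1 s2 s3 with s_i the SDs along the top-3 principal
    axes.  Degenerate (rank < 3) clouds return volume 0.  A warning — not an
    error — is issued when the top-3 PCs capture < 80% of total variance.
    """
    states = np.asarray(states, dtype=float)
    if states.shape[0] < 4 or states.shape[1] < 3:
        raise ValueError("need >= 4 trials and >= 3 channels")
    sds, var = _pca_sds(states)
    total = var.sum()
    captured = float(var[:3].sum() / total) if total > 0 else 0.0
    if total > 0 and var[2] / var[0] < rank_tol:
        return 0.0, captured
    volume = float(4.0 / 3.0 * np.pi * np.prod(sds[:3]))
    if captured < 0.8:
        warnings.warn(f"top-3 PCs capture only {captured:.1%} of variance",
                      stacklevel=2)
    return volume, captured


def normalized_volumes(volumes: dict) -> dict:
    """Each condition's ellipse volume divided by the maximum across conditions."""
    vmax = max(volumes.values())
    if vmax <= 0:
        raise ValueError("all volumes are zero; nothing to normalize")
    return {k: v / vmax for k, v in volumes.items()}


def _choose_k(var: np.ndarray, threshold: float = 0.8, cap: int = 10) -> int:
    frac = np.cumsum(var) / var.sum()
    return int(min(np.searchsorted(frac, threshold) + 1, cap, len(var)))


def proportion_md_explained(states: np.ndarray, mds: np.ndarray,
                            k: int | None = None) -> float:
    """Fraction of MD variance predictable from the preparatory state.

    States are projected onto the top-k PCs (k = smallest count capturing
    >= 80% of variance, capped at 10, unless given); MD is regressed on the
    scores with leave-one-out cross-validation (closed form via the hat
    matrix).  Returns max(0, 1 - PRESS / TSS), clipped to [0, 1].
    """
    states = np.asarray(states, dtype=float)
    mds = np.asarray(mds, dtype=float)
    n = len(mds)
    if n < 20:
        raise ValueError("need >= 20 trials for a stable estimate")
    tss = float(np.sum((mds - mds.mean()) ** 2))
    if tss == 0:
        raise ValueError("movement durations have zero variance")

    Xc = states - states.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (n - 1)
    if k is None:
        k = _choose_k(var)
    scores = U[:, :k] * s[:k]

    X = np.column_stack([np.ones(n), scores])
    beta, *_ = np.linalg.lstsq(X, mds, rcond=None)
    resid = mds - X @ beta
    # leave-one-out residuals: e_i / (1 - h_ii)
    Q, _ = np.linalg.qr(X)
    h = np.sum(Q ** 2, axis=1)
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    return float(np.clip(1.0 - press / tss, 0.0, 1.0))


def variance_f_test(md_a, md_b):
    """Two-sample two-sided F-test of equal variances: F = s_a^2 / s_b^2."""
    a = np.asarray(md_a, dtype=float)
    b = np.asarray(md_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator group")
    F = float(va / vb)
    dist = stats.f(len(a) - 1, len(b) - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return F, float(min(p, 1.0))


@dataclass
class PrepVariabilityResult:
    """Per-condition summary of the preparatory-variability pipeline."""

    volumes: dict
    normalized: dict
    captured: dict
    explained: dict
    md_mean: dict
    md_sd: dict
    f_statistic: float
    p_value: float


def preparatory_summary(set_small: NeuralTrialSet,
                        set_large: NeuralTrialSet) -> PrepVariabilityResult:
    """Full two-condition pipeline; asserts nothing about directionality."""
    sets = {"small": set_small, "large": set_large}
    volumes, captured, explained, md_mean, md_sd = {}, {}, {}, {}, {}
    for label, ts in sets.items():
        v, c = ellipse_volume(ts.rates)
        volumes[label] = v
        captured[label] = c
        explained[label] = proportion_md_explained(ts.rates, ts.md)
        md_mean[label] = float(ts.md.mean())
        md_sd[label] = float(ts.md.std(ddof=1))
    F, p = variance_f_test(set_small.md, set_large.md)
    return PrepVariabilityResult(volumes=volumes,
                                 normalized=normalized_volumes(volumes),
                                 captured=captured, explained=explained,
                                 md_mean=md_mean, md_sd=md_sd,
                                 f_statistic=F, p_value=p)


# ---------------------------------------------------------------------------
# small arithmetic helpers for interpreting the pipeline's outputs


def planning_md_reduction(explained_fraction: float, md_sd: float) -> float:
    """MD change (s) attributable to a one-SD shift of the planned component:
    explained_fraction * md_sd."""
    return explained_fraction * md_sd


def planning_share_of_gap(explained_fraction: float, md_sd: float,
                          md_gap: float) -> float:
    """Planning-attributable MD reduction as a fraction of a condition gap."""
    return planning_md_reduction(explained_fraction, md_sd) / md_gap


def coefficient_of_variation(sd: float, mean: float) -> float:
    return sd / mean
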