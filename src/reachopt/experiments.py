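"""In-silico reaching protocols: Fitts' law, profile asymmetry, ablations.

The Fitts protocol holds the reach amplitude fixed at A = 0.15 m and sweeps
the target width from 0.16 m down to 0.0141 m (index of difficulty 0.9 to
4.41 bits), optimizing an ensemble of reaches per width with the duration
penalty enabled.  Movement duration is read out per run, per-width means and
SDs are collected, and MD = a + b*ID is fit by least squares.

The speed-asymmetry protocol instead prescribes the movement duration
(fixed horizon, duration penalty off) and compares normalized velocity
profiles across fast/medium/slow reaches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .biomech import ArmModel, REF_POSE, Trajectory, default_arm, forward_kinematics, make_arm_model
from .control import CostConfig, Target
from .optimizer import OptimizerConfig, PlanResult, best_of, run_ensemble

__all__ = [
    "FittsConfig", "WidthStats", "FittsResult", "ProfileMetrics",
    "DEFAULT_WIDTHS", "index_of_difficulty", "make_target", "fit_fitts",
    "run_fitts", "fastest_trial_gap", "profile_metrics",
    "run_speed_asymmetry", "run_ablations", "correlate_with_reference",
]

#: Ten log-spaced target widths (m); IDs are then uniform in bits.
DEFAULT_WIDTHS = tuple(np.geomspace(0.16, 0.0141, 10))

MODEL_VARIANTS = ("muscle", "torque", "fl_const", "fv_const",
                  "muscles_removed", "no_effort")


def index_of_difficulty(A: float, W: float) -> float:
    """Task difficulty log2(2A/W) in bits."""
    if not (A > 0 and W > 0):
        raise ValueError("amplitude and width must be > 0")
    return math.log2(2.0 * A / W)


def make_target(width: float, amplitude: float = 0.15,
                arm=None, q_start=REF_POSE) -> Target:
    """Target centered ``amplitude`` meters outward (+x) of the start hand.

    The outward direction engages shoulder extension with elbow extension, a
    coordination the lumped muscle set produces smoothly from the flexed
    start posture.
    """
    arm = arm or default_arm()
    start = forward_kinematics(np.asarray(q_start), arm)
    center = start + np.array([amplitude, 0.0])
    return Target(center=center, width=width, amplitude=amplitude)


@dataclass
class FittsConfig:
    amplitude: float = 0.15
    widths: tuple = DEFAULT_WIDTHS
    runs_per_width: int = 10
    horizon: float = 1.0
    variant: str = "muscle"
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if not all(0 < w <= 2 * self.amplitude for w in self.widths):
            raise ValueError("widths must be positive and <= 2A")
        if self.runs_per_width < 2:
            raise ValueError("need >= 2 runs per width for SD estimates")
        if self.variant not in MODEL_VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class WidthStats:
    width: float
    id_bits: float
    mds: np.ndarray  # per-run MDs of runs that acquired the target (s)
    hit_rate: float

    @property
    def md_mean(self) -> float | None:
        return float(np.mean(self.mds)) if self.mds.size else None

    @property
    def md_sd(self) -> float | None:
        return float(np.std(self.mds, ddof=1)) if self.mds.size >= 2 else None


@dataclass
class FittsResult:
    per_width: list[WidthStats]
    a: float | None  # intercept (s)
    b: float | None  # slope (s/bit)
    r_squared: float | None
    variant: str
    excluded_widths: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"width": w.width, "id_bits": w.id_bits,
                 "md_mean": w.md_mean, "md_sd": w.md_sd,
                 "n_hits": w.mds.size, "hit_rate": w.hit_rate}
                for w in self.per_width]
        return pd.DataFrame(rows)


def fit_fitts(ids, md_means):
    """Ordinary least squares of MD on ID: returns (a, b, R^2)."""
    ids = np.asarray(ids, dtype=float)
    md = np.asarray(md_means, dtype=float)
    if ids.size < 2 or np.ptp(ids) == 0:
        raise ValueError("need >= 2 distinct index-of-difficulty levels")
    res = stats.linregress(ids, md)
    return float(res.intercept), float(res.slope), float(res.rvalue ** 2)


def _cost_for_variant(variant: str, base: CostConfig | None = None) -> CostConfig:
    cfg = base or CostConfig(duration_on=True, hit_radius_mode=True)
    if variant == "no_effort":
        cfg = replace(cfg, w2=0.0)
    return cfg


def run_fitts(cfg: FittsConfig, opt_cfg: OptimizerConfig | None = None,
              base_seed: int = 0, model: ArmModel | None = None,
              cost_cfg: CostConfig | None = None) -> FittsResult:
    """Full speed-accuracy protocol: ensembles per width, stats, Fitts fit.

    Runs whose hand never settles inside the target contribute to the hit
    rate but are excluded from the MD statistics; widths with fewer than two
    acquiring runs are excluded from the fit and flagged.
    """
    model = model or make_arm_model(cfg.variant)
    cost = _cost_for_variant(cfg.variant, cost_cfg)
    opt_cfg = opt_cfg or OptimizerConfig.reduced()

    per_width = []
    for j, w in enumerate(cfg.widths):
        target = make_target(w, cfg.amplitude, model.arm)
        results = run_ensemble(cfg.runs_per_width, base_seed + j * 1_000_003,
                               model, target, cfg.horizon, cost, opt_cfg,
                               dt=cfg.dt)
        mds = np.array([r.md for r in results if r.md is not None])
        per_width.append(WidthStats(
            width=float(w), id_bits=index_of_difficulty(cfg.amplitude, w),
            mds=mds, hit_rate=mds.size / len(results)))

    usable = [ws for ws in per_width if ws.mds.size >= 2]
    excluded = [ws.width for ws in per_width if ws.mds.size < 2]
    if len(usable) >= 2:
        a, b, r2 = fit_fitts([ws.id_bits for ws in usable],
                             [ws.md_mean for ws in usable])
    else:
        a = b = r2 = None
    return FittsResult(per_width=per_width, a=a, b=b, r_squared=r2,
                       variant=cfg.variant, excluded_widths=excluded)


def fastest_trial_gap(stats_small: WidthStats, stats_large: WidthStats) -> float:
    """min MD(small target) - min MD(large target): the limb-dynamics floor.

    May be negative under few runs; callers should treat that as a flag.
    """
    if not (stats_small.mds.size and stats_large.mds.size):
        raise ValueError("both widths need at least one target acquisition")
    return float(np.min(stats_small.mds) - np.min(stats_large.mds))


# ---------------------------------------------------------------------------
# velocity profiles


@dataclass
class ProfileMetrics:
    rel_peak_time: float  # time of peak speed as a fraction of MD
    n_local_minima: int  # interior minima of the smoothed profile
    norm_time: np.ndarray
    norm_speed: np.ndarray


def profile_metrics(times, speeds, md: float,
                    smooth_frac: float = 0.05) -> ProfileMetrics:
    """Normalize a hand-speed profile over [0, MD] and summarize its shape.

    The profile is normalized by its peak speed and time by MD; local minima
    are counted on a moving-average-smoothed copy, restricted to the interior
    5-95% of the movement so endpoint noise is ignored.
    """
    times = np.asarray(times, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    mask = times <= md + 1e-12
    t = times[mask]
    v = speeds[mask]
    peak = v.max()
    if peak <= 0:
        raise ValueError("profile has zero peak speed")
    nt = t / md
    nv = v / peak
    rel_peak = float(nt[np.argmax(nv)])

    win = max(1, int(round(smooth_frac * len(nv))))
    if win > 1:
        kernel = np.ones(win) / win
        sv = np.convolve(nv, kernel, mode="same")
    else:
        sv = nv
    lo, hi = int(0.05 * len(sv)), int(0.95 * len(sv))
    seg = sv[lo:hi]
    interior = (seg[1:-1] < seg[:-2]) & (seg[1:-1] < seg[2:])
    return ProfileMetrics(rel_peak_time=rel_peak,
                          n_local_minima=int(np.sum(interior)),
                          norm_time=nt, norm_speed=nv)


def trajectory_profile_metrics(traj: Trajectory, md: float | None = None,
                               smooth_frac: float = 0.05) -> ProfileMetrics:
    """Profile metrics of a simulated trajectory (MD defaults to the horizon)."""
    return profile_metrics(traj.t, traj.speed, md if md is not None else traj.T,
                           smooth_frac)


def run_speed_asymmetry(mds=(0.18, 0.22, 0.26), runs_per_md: int = 10,
                        model: ArmModel | None = None,
                        opt_cfg: OptimizerConfig | None = None,
                        base_seed: int = 0, width: float = 0.04,
                        amplitude: float = 0.15,
                        dt: float = 1e-3) -> dict[float, ProfileMetrics]:
    """Fixed-duration reaches at prescribed MDs; metrics of best-of-ensemble.

    The horizon equals the prescribed MD and the duration penalty is off, so
    every solution *is* a reach of that duration; the question is only how
    the speed profile is shaped.
    """
    if not all(b > a for a, b in zip(mds, mds[1:])):
        raise ValueError("prescribed MDs must be increasing")
    model = model or make_arm_model("muscle")
    opt_cfg = opt_cfg or OptimizerConfig.reduced()
    cost = CostConfig(duration_on=False, hit_radius_mode=True)
    target = make_target(width, amplitude, model.arm)

    out: dict[float, ProfileMetrics] = {}
    for j, md in enumerate(mds):
        results = run_ensemble(runs_per_md, base_seed + j * 1_000_003,
                               model, target, md, cost, opt_cfg, dt=dt)
        hits = [r for r in results if r.hit] or results
        best = best_of(hits)
        out[float(md)] = trajectory_profile_metrics(best.trajectory, md)
    return out


def run_ablations(variants=("muscle", "torque", "fl_const", "muscles_removed",
                            "no_effort"),
                  cfg: FittsConfig | None = None,
                  opt_cfg: OptimizerConfig | None = None,
                  base_seed: int = 0) -> dict[str, FittsResult]:
    """Fitts protocol across plant/cost ablations (the model-impact grid)."""
    cfg = cfg or FittsConfig()
    return {v: run_fitts(replace(cfg, variant=v), opt_cfg, base_seed)
            for v in variants}


def correlate_with_reference(fitts: FittsResult, reference: pd.DataFrame):
    """Pearson correlation of model MD means and SDs with a behavioral table.

    ``reference`` needs columns subject, index_of_difficulty,
    movement_duration; per-ID means/SDs are computed across subjects and the
    model's curves are linearly interpolated onto the reference ID grid.
    Returns (r_means, p_means, r_sds, p_sds).
    """
    required = {"subject", "index_of_difficulty", "movement_duration"}
    if not required.issubset(reference.columns):
        raise ValueError(f"reference table needs columns {sorted(required)}")
    grouped = reference.groupby("index_of_difficulty")["movement_duration"]
    ref_ids = np.array(sorted(grouped.groups))
    ref_means = grouped.mean().loc[ref_ids].to_numpy()
    ref_sds = grouped.std(ddof=1).loc[ref_ids].to_numpy()

    usable = [ws for ws in fitts.per_width if ws.mds.size >= 2]
    ids = np.array([ws.id_bits for ws in usable])
    order = np.argsort(ids)
    ids = ids[order]
    means = np.array([usable[i].md_mean for i in order])
    sds = np.array([usable[i].md_sd for i in order])

    model_means = np.interp(ref_ids, ids, means)
    model_sds = np.interp(ref_ids, ids, sds)
    r_m, p_m = stats.pearsonr(model_means, ref_means)
    r_s, p_s = stats.pearsonr(model_sds, ref_sds)
    return float(r_m), float(p_m), float(r_s), float(p_s)
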