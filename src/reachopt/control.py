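"""Cubic B-spline control plans and the trajectory cost function.

A plan is a matrix of spline knots (one row per actuator, one column per
basis function) on a clamped uniform cubic B-spline over the movement
horizon.  The cost that scores a rollout combines endpoint accuracy, summed
squared activations ("effort"), joint-limit violations, terminal velocity,
an optional terminal-posture term, and — for speed-accuracy experiments — a
per-step penalty for time spent outside the target.

The effort and terminal-velocity terms are *gated*: they are replaced by a
large constant C whenever the final hand position misses the target region
by more than a tolerance zeta, so the optimizer always prioritizes actually
reaching the target before polishing secondary objectives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline

from .biomech import ArmParams, Trajectory

__all__ = [
    "ControlPlan",
    "Target",
    "CostConfig",
    "CostBreakdown",
    "n_knots_for_horizon",
    "make_plan",
    "eval_plan",
    "delta_gate",
    "joint_limit_penalty",
    "terminal_posture_penalty",
    "duration_penalty",
    "evaluate_cost",
    "movement_duration",
]

SPLINE_DEGREE = 3


def n_knots_for_horizon(T: float, interval: float = 0.1) -> int:
    """Number of free spline coefficients per actuator for horizon T."""
    n_seg = max(1, math.ceil(T / interval - 1e-9))
    return n_seg + SPLINE_DEGREE


@lru_cache(maxsize=64)
def _knot_vector(T: float, n_coef: int) -> tuple[float, ...]:
    n_seg = n_coef - SPLINE_DEGREE
    bp = np.linspace(0.0, T, n_seg + 1)
    t = np.concatenate([[0.0] * SPLINE_DEGREE, bp, [T] * SPLINE_DEGREE])
    return tuple(t)


@dataclass
class ControlPlan:
    """Clamped cubic B-spline excitation (or torque) plan.

    ``knots`` has shape (n_actuators, n_coef).  Evaluation clips to [0, 1]
    in muscle mode and to [-1, 1] in torque mode; the optimizer searches the
    unbounded knot space and relies on this clipping.
    """

    knots: np.ndarray
    T: float
    interval: float = 0.1
    mode: str = "muscle"  # "muscle" | "torque"

    def __post_init__(self) -> None:
        self.knots = np.atleast_2d(np.asarray(self.knots, dtype=float))
        expected = n_knots_for_horizon(self.T, self.interval)
        if self.knots.shape[1] != expected:
            raise ValueError(
                f"expected {expected} knots per actuator for T={self.T}, "
                f"interval={self.interval}; got {self.knots.shape[1]}")
        if not np.all(np.isfinite(self.knots)):
            raise ValueError("knot values must be finite")

    @property
    def n_actuators(self) -> int:
        return self.knots.shape[0]

    def basis_matrix(self, ts: np.ndarray) -> np.ndarray:
        """(len(ts), n_coef) matrix of B-spline basis values."""
        t = np.asarray(_knot_vector(self.T, self.knots.shape[1]))
        return BSpline.design_matrix(
            np.asarray(ts, dtype=float), t, SPLINE_DEGREE).toarray()

    def evaluate(self, ts) -> np.ndarray:
        """Spline outputs at times ``ts``, clipped per actuation mode."""
        ts_arr = np.atleast_1d(np.asarray(ts, dtype=float))
        if ts_arr.min() < -1e-12 or ts_arr.max() > self.T + 1e-12:
            raise ValueError(f"evaluation times must lie in [0, {self.T}]")
        B = self.basis_matrix(np.clip(ts_arr, 0.0, self.T))
        out = B @ self.knots.T  # (len(ts), n_actuators)
        if self.mode == "torque":
            out = np.clip(out, -1.0, 1.0)
        else:
            out = np.clip(out, 0.0, 1.0)
        return out


def make_plan(values: float | np.ndarray, n_actuators: int, T: float,
              interval: float = 0.1, mode: str = "muscle") -> ControlPlan:
    """Build a plan from a constant value or a flat/matrix knot array."""
    k = n_knots_for_horizon(T, interval)
    values = np.asarray(values, dtype=float)
    if values.ndim == 0:
        knots = np.full((n_actuators, k), float(values))
    else:
        knots = values.reshape(n_actuators, k)
    return ControlPlan(knots=knots, T=T, interval=interval, mode=mode)


def eval_plan(plan: ControlPlan, t: float) -> np.ndarray:
    """Excitation vector at time ``t`` (convenience scalar-time wrapper)."""
    return plan.evaluate(t)[0]


# ---------------------------------------------------------------------------
# targets and cost


@dataclass
class Target:
    """Circular target: center (m), width W (m); acceptance radius is W/2."""

    center: np.ndarray
    width: float
    amplitude: float | None = None  # distance from the start position, if known

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not self.width > 0:
            raise ValueError("target width must be > 0")

    @property
    def kappa(self) -> float:
        return self.width / 2.0


@dataclass
class CostConfig:
    """Weights and constants of the trajectory cost.

    w1..w5 weight endpoint error, gated effort, joint limits, gated terminal
    velocity, and terminal posture.  ``zeta`` (m) is the miss tolerance of
    the gate and ``C`` the gate constant.  ``w_time`` scales the per-step
    out-of-target penalty used when ``duration_on``; ``hit_radius_mode``
    zeroes the endpoint term once the hand ends anywhere inside the target.
    """

    w1: float = 5.0
    w2: float = 1e-3
    w3: float = 1e-5
    w4: float = 0.15
    w5: float = 0.5
    zeta: float = 0.025
    C: float = 1e6
    w_time: float = 0.2
    duration_on: bool = False
    hit_radius_mode: bool = False
    posture_enabled: bool = False
    posture_ref: float | None = None
    posture_joint: int = 1

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3", "w4", "w5", "w_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be >= 0")
        if not self.zeta > 0:
            raise ValueError("zeta must be > 0")
        if self.posture_enabled and self.posture_ref is None:
            raise ValueError("posture term enabled without a reference angle")


@dataclass
class CostBreakdown:
    endpoint: float
    effort: float
    joint_limit: float
    terminal_velocity: float
    posture: float
    duration: float

    @property
    def total(self) -> float:
        return (self.endpoint + self.effort + self.joint_limit
                + self.terminal_velocity + self.posture + self.duration)

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in
             self.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        d["total"] = self.total
        return d


def delta_gate(x: float, miss_distance: float, cfg: CostConfig) -> float:
    """Return ``x`` when the final miss is within zeta, else the constant C."""
    return float(x) if miss_distance < cfg.zeta else cfg.C


def joint_limit_penalty(q, arm: ArmParams) -> float:
    """Quadratic penalty on joint-limit violations, summed over joints.

    Accepts a single pose (2,) or a pose series (N, 2); a series returns the
    sum over all steps.
    """
    q = np.asarray(q, dtype=float)
    lo = np.asarray(arm.q_lower)
    hi = np.asarray(arm.q_upper)
    below = np.clip(lo - q, 0.0, None)
    above = np.clip(q - hi, 0.0, None)
    return float(np.sum(below ** 2) + np.sum(above ** 2))


def terminal_posture_penalty(qN, cfg: CostConfig) -> float:
    """Squared deviation of one designated joint coordinate from its reference.

    Disabled by default for the planar arm (no pronation coordinate exists);
    kept in the cost for completeness.
    """
    if not cfg.posture_enabled:
        return 0.0
    if cfg.posture_ref is None:
        raise ValueError("posture term enabled without a reference angle")
    qN = np.asarray(qN, dtype=float)
    return float((qN[cfg.posture_joint] - cfg.posture_ref) ** 2)


def _outside_mask(traj: Trajectory, target: Target) -> np.ndarray:
    dist = np.linalg.norm(traj.hand - target.center, axis=1)
    return dist >= target.kappa


def duration_penalty(traj: Trajectory, target: Target) -> int:
    """Number of trajectory samples with the hand outside the target region."""
    return int(np.sum(_outside_mask(traj, target)))


def movement_duration(traj: Trajectory, target: Target) -> float | None:
    """Time of first entry of the hand into the target region, or None.

    The duration is read out the moment the hand position first comes within
    the acceptance radius; a trajectory that never enters has no movement
    duration.  (The per-step duration penalty, not this readout, is what
    pressures solutions to stay inside afterwards.)
    """
    outside = _outside_mask(traj, target)
    inside_idx = np.nonzero(~outside)[0]
    if inside_idx.size == 0:
        return None
    return float(traj.t[inside_idx[0]])


def evaluate_cost(traj: Trajectory, target: Target, cfg: CostConfig,
                  arm: ArmParams) -> CostBreakdown:
    """Assemble the full cost breakdown for a completed rollout.

    Both gates key on the same final miss distance ||hN - target center||.
    ``arm`` supplies the joint limits for the limit-violation term.
    """
    miss = float(np.linalg.norm(traj.hand[-1] - target.center))

    if cfg.hit_radius_mode and miss < target.kappa:
        endpoint = 0.0
    else:
        endpoint = cfg.w1 * miss ** 2

    act_sq = float(np.sum(traj.activations ** 2)) if traj.activations.size else 0.0
    effort = cfg.w2 * delta_gate(act_sq, miss, cfg)

    jl = cfg.w3 * joint_limit_penalty(traj.q, arm)
    term_vel = cfg.w4 * delta_gate(float(np.sum(traj.qd[-1] ** 2)), miss, cfg)
    posture = cfg.w5 * terminal_posture_penalty(traj.q[-1], cfg)
    duration = cfg.w_time * duration_penalty(traj, target) if cfg.duration_on else 0.0
    return CostBreakdown(endpoint=endpoint, effort=effort, joint_limit=jl,
                         terminal_velocity=term_vel, posture=posture,
                         duration=duration)
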