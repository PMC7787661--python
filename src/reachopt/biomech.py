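"""Planar two-joint arm driven by joint torques or lumped Hill-type muscles.

The plant is a desk-scale stand-in for a full upper-extremity musculoskeletal
model: two rigid links (upper arm, forearm+hand) moving in a plane, actuated
either directly by joint torques or by six lumped muscle-tendon units
(shoulder flexor/extensor, elbow flexor/extensor, and a biarticular
flexor/extensor pair) with constant moment arms.  It keeps the mechanisms
that matter for speed-accuracy experiments — the active force-length curve,
the force-velocity relation with its eccentric branch, first-order
activation dynamics, and muscle redundancy — while staying cheap enough to
run thousands of forward rollouts per optimization.

Integration uses a fixed-step semi-explicit Euler scheme (velocities updated
before positions), which makes rollouts bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernel import rollout_kernel

__all__ = [
    "ArmParams",
    "MuscleParams",
    "ArmState",
    "ArmModel",
    "Trajectory",
    "SimulationDiverged",
    "forward_kinematics",
    "hand_jacobian",
    "hand_speed",
    "force_length",
    "force_velocity",
    "passive_force",
    "muscle_force",
    "activation_derivative",
    "fiber_length",
    "fiber_velocity",
    "arm_dynamics",
    "simulate",
    "default_arm",
    "default_muscles",
    "make_arm_model",
    "REF_POSE",
]

#: Reference posture (rad): shoulder 45 deg, elbow 90 deg.  Muscles are at
#: optimal fiber length here; it is also the default start pose for reaches.
REF_POSE = (math.pi / 4.0, math.pi / 2.0)

# Force-velocity curvature constants (normalized Hill hyperbola).
FV_SHORTENING_CURVATURE = 0.25
FV_ECCENTRIC_CURVATURE = 0.25


@dataclass
class ArmParams:
    """Physical parameters of the two-link planar arm.

    Lengths in m, masses in kg, inertias about the link COM in kg m^2,
    joint limits in rad, damping in N m s/rad, torque limit in N m.
    """

    lengths: tuple[float, float] = (0.30, 0.33)
    masses: tuple[float, float] = (2.0, 1.5)
    inertias: tuple[float, float] = (0.015, 0.0136)
    com_offsets: tuple[float, float] = (0.15, 0.165)
    q_lower: tuple[float, float] = (-1.0, 0.0)
    q_upper: tuple[float, float] = (3.0, 2.9)
    damping: float = 1.5
    gravity: bool = False
    tau_max: float = 50.0

    def __post_init__(self) -> None:
        for name in ("lengths", "masses", "inertias", "com_offsets"):
            vals = getattr(self, name)
            if not all(v > 0 for v in vals):
                raise ValueError(f"{name} must be strictly positive, got {vals}")
        for lo, hi in zip(self.q_lower, self.q_upper):
            if not lo < hi:
                raise ValueError(f"joint limits require lower < upper, got {lo} >= {hi}")
        if not self.tau_max > 0:
            raise ValueError("tau_max must be > 0")
        if self.damping < 0:
            raise ValueError("damping must be >= 0")


@dataclass
class MuscleParams:
    """One lumped Hill-type muscle-tendon unit with constant moment arms.

    ``moment_arms`` is signed, one entry per joint (m); a zero entry means the
    muscle does not span that joint.  ``vmax`` is the maximal shortening
    velocity in optimal fiber lengths per second.
    """

    name: str
    fmax: float
    lopt: float = 0.15
    vmax: float = 10.0
    tau_act: float = 0.015
    tau_deact: float = 0.050
    moment_arms: tuple[float, float] = (0.0, 0.0)
    fl_width: float = 0.45
    ecc_plateau: float = 1.5
    passive_coef: float = 0.5

    def __post_init__(self) -> None:
        if not self.fmax > 0:
            raise ValueError(f"{self.name}: fmax must be > 0")
        if not (self.tau_act > 0 and self.tau_deact > 0):
            raise ValueError(f"{self.name}: time constants must be > 0")
        if not any(r != 0.0 for r in self.moment_arms):
            raise ValueError(f"{self.name}: at least one moment arm must be nonzero")
        if not (self.lopt > 0 and self.vmax > 0):
            raise ValueError(f"{self.name}: lopt and vmax must be > 0")


@dataclass
class ArmState:
    """Joint angles (rad), joint velocities (rad/s) and muscle activations."""

    q: np.ndarray
    qd: np.ndarray
    activations: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.qd = np.asarray(self.qd, dtype=float)
        self.activations = np.asarray(self.activations, dtype=float)
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qd))):
            raise ValueError("state must be finite")
        if self.activations.size and (
            self.activations.min() < 0 or self.activations.max() > 1
        ):
            raise ValueError("activations must lie in [0, 1]")


@dataclass
class ArmModel:
    """An arm plus its actuation: a muscle set, or direct joint torques.

    ``fl_const`` replaces the active force-length curve by 1 everywhere (the
    "unrealistic force-length" ablation); ``fv_const`` does the same for the
    force-velocity relation.
    """

    arm: ArmParams
    muscles: list[MuscleParams] = field(default_factory=list)
    mode: str = "muscle"  # "muscle" | "torque"
    fl_const: bool = False
    fv_const: bool = False
    q_ref: tuple[float, float] = REF_POSE

    def __post_init__(self) -> None:
        if self.mode not in ("muscle", "torque"):
            raise ValueError(f"unknown actuation mode {self.mode!r}")
        if self.mode == "muscle" and not self.muscles:
            raise ValueError("muscle mode requires at least one muscle")

    @property
    def n_actuators(self) -> int:
        return len(self.muscles) if self.mode == "muscle" else 2


@dataclass
class Trajectory:
    """Time series of a forward rollout plus derived hand kinematics."""

    t: np.ndarray  # (N+1,)
    q: np.ndarray  # (N+1, 2)
    qd: np.ndarray  # (N+1, 2)
    activations: np.ndarray  # (N+1, M); empty in torque mode
    excitations: np.ndarray  # (N+1, n_actuators), post-clipping
    hand: np.ndarray  # (N+1, 2)
    speed: np.ndarray  # (N+1,)
    T: float
    dt: float

    @property
    def n_steps(self) -> int:
        return len(self.t) - 1


class SimulationDiverged(RuntimeError):
    """Raised when the integrator produces a non-finite state."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"integration diverged at step {step}")


# ---------------------------------------------------------------------------
# kinematics


def forward_kinematics(q, arm: ArmParams) -> np.ndarray:
    """Planar endpoint of the two-link chain, shoulder at the origin.

    ``q`` may be a single (2,) pose or an (N, 2) series.
    """
    q = np.asarray(q, dtype=float)
    l1, l2 = arm.lengths
    q1 = q[..., 0]
    q12 = q[..., 0] + q[..., 1]
    x = l1 * np.cos(q1) + l2 * np.cos(q12)
    y = l1 * np.sin(q1) + l2 * np.sin(q12)
    return np.stack([x, y], axis=-1)


def hand_jacobian(q, arm: ArmParams) -> np.ndarray:
    """2x2 Jacobian of the hand position with respect to joint angles."""
    q = np.asarray(q, dtype=float)
    l1, l2 = arm.lengths
    s1, c1 = np.sin(q[..., 0]), np.cos(q[..., 0])
    s12, c12 = np.sin(q[..., 0] + q[..., 1]), np.cos(q[..., 0] + q[..., 1])
    J = np.empty(q.shape[:-1] + (2, 2))
    J[..., 0, 0] = -l1 * s1 - l2 * s12
    J[..., 0, 1] = -l2 * s12
    J[..., 1, 0] = l1 * c1 + l2 * c12
    J[..., 1, 1] = l2 * c12
    return J


def hand_speed(traj: Trajectory, arm: ArmParams | None = None,
               method: str = "jacobian") -> np.ndarray:
    """Per-step magnitude of the hand velocity (m/s).

    ``method="jacobian"`` uses J(q) qdot; ``method="fd"`` uses central finite
    differences of the stored hand positions (one-sided at the ends).  The two
    agree to O(dt) and the agreement is asserted in tests.
    """
    if traj.n_steps < 1:
        raise ValueError("hand_speed needs at least 2 trajectory steps")
    if method == "jacobian":
        if arm is None:
            raise ValueError("jacobian method needs ArmParams")
        J = hand_jacobian(traj.q, arm)
        v = np.einsum("nij,nj->ni", J, traj.qd)
        return np.linalg.norm(v, axis=-1)
    if method == "fd":
        v = np.gradient(traj.hand, traj.t, axis=0)
        return np.linalg.norm(v, axis=-1)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# muscle mechanics


def force_length(l_norm, width: float = 0.45, const: bool = False):
    """Active force-length scaling: Gaussian bell, maximum 1 at optimal length.

    With ``const=True`` (the ablation) the curve is flat at 1 for all lengths.
    """
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm <= 0):
        raise ValueError("normalized fiber length must be > 0")
    if const:
        return np.ones_like(l_norm)[()] if l_norm.ndim else 1.0
    out = np.exp(-(((l_norm - 1.0) / width) ** 2))
    return out[()] if out.ndim == 0 else out


def force_velocity(v_norm, vmax: float = 10.0, ecc_plateau: float = 1.5,
                   const: bool = False):
    """Force-velocity scaling; ``v_norm`` in optimal lengths/s, shortening < 0.

    Shortening branch: normalized Hill hyperbola reaching 0 at -vmax.
    Lengthening branch: rises above 1 and saturates at ``ecc_plateau`` — the
    eccentric force enhancement that lets muscles brake late in fast reaches.
    Monotone non-decreasing in v_norm.
    """
    v_norm = np.asarray(v_norm, dtype=float)
    if const:
        return np.ones_like(v_norm)[()] if v_norm.ndim else 1.0
    vn = v_norm / vmax
    ks, ke = FV_SHORTENING_CURVATURE, FV_ECCENTRIC_CURVATURE
    short = np.clip((1.0 + vn) / (1.0 - vn / ks), 0.0, None)
    ecc = 1.0 + (ecc_plateau - 1.0) * vn / (vn + ke)
    out = np.where(vn < 0, short, ecc)
    return out[()] if out.ndim == 0 else out


def passive_force(l_norm, coef: float = 0.5):
    """Normalized passive elastic force: zero below optimal length, quadratic above."""
    l_norm = np.asarray(l_norm, dtype=float)
    out = np.where(l_norm > 1.0, coef * (l_norm - 1.0) ** 2, 0.0)
    return out[()] if out.ndim == 0 else out


def muscle_force(a: float, l_norm: float, v_norm: float, p: MuscleParams,
                 fl_const: bool = False, fv_const: bool = False) -> float:
    """Tension (N) of one muscle: a*Fmax*fl*fv plus the passive term."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"activation {a} outside [0, 1]")
    active = a * p.fmax * force_length(l_norm, p.fl_width, fl_const) * \
        force_velocity(v_norm, p.vmax, p.ecc_plateau, fv_const)
    return float(active + p.fmax * passive_force(l_norm, p.passive_coef))


def activation_derivative(e: float, a: float, p: MuscleParams) -> float:
    """First-order activation dynamics (e - a)/tau, faster on the way up."""
    if not (0.0 <= e <= 1.0 and 0.0 <= a <= 1.0):
        raise ValueError("excitation and activation must lie in [0, 1]")
    tau = p.tau_act if e > a else p.tau_deact
    return (e - a) / tau


def fiber_length(q, p: MuscleParams, q_ref=REF_POSE) -> float:
    """Fiber length (m) under the constant-moment-arm path model."""
    q = np.asarray(q, dtype=float)
    r = np.asarray(p.moment_arms)
    return float(p.lopt - r @ (q - np.asarray(q_ref)))


def fiber_velocity(qd, p: MuscleParams) -> float:
    """Fiber lengthening velocity (m/s); shortening is negative."""
    return float(-np.asarray(p.moment_arms) @ np.asarray(qd, dtype=float))


# ---------------------------------------------------------------------------
# dynamics


def arm_dynamics(state: ArmState, torques, arm: ArmParams) -> np.ndarray:
    """Joint accelerations of the two-link arm under the given joint torques.

    Torques are clipped to +/- tau_max before use.  Includes Coriolis and
    centrifugal terms, viscous damping, and gravity when enabled.
    """
    q, qd = state.q, state.qd
    tau = np.clip(np.asarray(torques, dtype=float), -arm.tau_max, arm.tau_max)
    l1, _ = arm.lengths
    m1, m2 = arm.masses
    I1, I2 = arm.inertias
    d1, d2 = arm.com_offsets
    c2 = math.cos(q[1])
    s2 = math.sin(q[1])

    m11 = I1 + I2 + m1 * d1 ** 2 + m2 * (l1 ** 2 + d2 ** 2 + 2 * l1 * d2 * c2)
    m12 = I2 + m2 * (d2 ** 2 + l1 * d2 * c2)
    m22 = I2 + m2 * d2 ** 2
    det = m11 * m22 - m12 * m12
    assert det > 0, "mass matrix must be positive definite for valid params"

    h = m2 * l1 * d2 * s2
    cor1 = -h * qd[1] * (2 * qd[0] + qd[1])
    cor2 = h * qd[0] ** 2

    if arm.gravity:
        g = 9.81
        c1 = math.cos(q[0])
        c12 = math.cos(q[0] + q[1])
        g1 = (m1 * d1 + m2 * l1) * g * c1 + m2 * d2 * g * c12
        g2 = m2 * d2 * g * c12
    else:
        g1 = g2 = 0.0

    rhs1 = tau[0] - cor1 - g1 - arm.damping * qd[0]
    rhs2 = tau[1] - cor2 - g2 - arm.damping * qd[1]
    qdd1 = (m22 * rhs1 - m12 * rhs2) / det
    qdd2 = (m11 * rhs2 - m12 * rhs1) / det
    return np.array([qdd1, qdd2])


def _pack_muscles(model: ArmModel):
    ms = model.muscles
    return (
        np.array([m.fmax for m in ms]),
        np.array([m.lopt for m in ms]),
        np.array([m.vmax for m in ms]),
        np.array([m.tau_act for m in ms]),
        np.array([m.tau_deact for m in ms]),
        np.array([m.moment_arms for m in ms]),
        np.array([m.fl_width for m in ms]),
        np.array([m.ecc_plateau for m in ms]),
        np.array([m.passive_coef for m in ms]),
    )


def simulate(plan, model: ArmModel, T: float, dt: float = 1e-3,
             initial_state: ArmState | None = None) -> Trajectory:
    """Semi-explicit Euler rollout of a control plan on the arm.

    In muscle mode the plan's spline outputs are clipped to [0, 1] and drive
    the activation ODE; muscle tensions map to joint torques through the
    constant moment arms.  In torque mode the outputs are clipped to [-1, 1]
    and scaled by tau_max.  Deterministic given identical inputs.

    Raises :class:`SimulationDiverged` if a non-finite state appears.
    """
    if not (T > 0 and dt > 0):
        raise ValueError("T and dt must be > 0")
    if plan.T < T - 1e-12:
        raise ValueError(f"plan horizon {plan.T} shorter than simulation horizon {T}")
    n = int(round(T / dt))
    ts = np.arange(n + 1) * dt
    U = plan.evaluate(ts)  # (N+1, n_actuators), already clipped per mode

    if initial_state is None:
        q0 = np.array(REF_POSE)
        qd0 = np.zeros(2)
    else:
        q0 = initial_state.q.copy()
        qd0 = initial_state.qd.copy()

    arm = model.arm
    if model.mode == "muscle":
        fmax, lopt, vmax, ta, td, R, flw, ecc, pc = _pack_muscles(model)
    else:
        M = 1  # dummy muscle arrays for the kernel signature
        fmax = lopt = vmax = ta = td = flw = ecc = pc = np.ones(M)
        R = np.zeros((M, 2))

    q, qd, act, fail = rollout_kernel(
        np.ascontiguousarray(U, dtype=float), q0, qd0, dt,
        arm.lengths[0], arm.masses[0], arm.masses[1],
        arm.inertias[0], arm.inertias[1],
        arm.com_offsets[0], arm.com_offsets[1],
        arm.damping, 9.81 if arm.gravity else 0.0, arm.tau_max,
        fmax, lopt, vmax, ta, td, R,
        np.asarray(model.q_ref, dtype=float), flw, ecc, pc,
        FV_SHORTENING_CURVATURE, FV_ECCENTRIC_CURVATURE,
        model.fl_const, model.fv_const, model.mode == "torque",
    )
    if fail >= 0:
        raise SimulationDiverged(int(fail))

    hand = forward_kinematics(q, arm)
    J = hand_jacobian(q, arm)
    speed = np.linalg.norm(np.einsum("nij,nj->ni", J, qd), axis=-1)
    if model.mode == "torque":
        exc = np.clip(U, -1.0, 1.0)
        act_out = np.zeros((n + 1, 0))
    else:
        exc = np.clip(U, 0.0, 1.0)
        act_out = act
    return Trajectory(t=ts, q=q, qd=qd, activations=act_out, excitations=exc,
                      hand=hand, speed=speed, T=T, dt=dt)


# ---------------------------------------------------------------------------
# default plant


def default_arm(**overrides) -> ArmParams:
    return ArmParams(**overrides)


def default_muscles() -> list[MuscleParams]:
    """Six lumped muscles spanning shoulder, elbow, and both joints."""
    return [
        MuscleParams("shoulder_flexor", fmax=1000.0, moment_arms=(0.04, 0.0)),
        MuscleParams("shoulder_extensor", fmax=1000.0, moment_arms=(-0.04, 0.0)),
        MuscleParams("elbow_flexor", fmax=800.0, moment_arms=(0.0, 0.03)),
        MuscleParams("elbow_extensor", fmax=800.0, moment_arms=(0.0, -0.025)),
        MuscleParams("biarticular_flexor", fmax=600.0, moment_arms=(0.03, 0.03)),
        MuscleParams("biarticular_extensor", fmax=600.0, moment_arms=(-0.03, -0.03)),
    ]


def make_arm_model(variant: str = "muscle", arm: ArmParams | None = None) -> ArmModel:
    """Build a plant variant for the ablation grid.

    Variants: ``muscle`` (full model), ``torque`` (direct joint torques),
    ``fl_const`` (flat force-length), ``fv_const`` (flat force-velocity),
    ``muscles_removed`` (biarticular pair dropped).  The ``no_effort``
    ablation changes the cost, not the plant, and maps to ``muscle`` here.
    """
    arm = arm or default_arm()
    if variant == "torque":
        return ArmModel(arm=arm, muscles=[], mode="torque")
    muscles = default_muscles()
    if variant == "muscles_removed":
        muscles = [m for m in muscles if not m.name.startswith("biarticular")]
    model = ArmModel(arm=arm, muscles=muscles, mode="muscle")
    if variant == "fl_const":
        model.fl_const = True
    elif variant == "fv_const":
        model.fv_const = True
    elif variant not in ("muscle", "muscles_removed", "no_effort"):
        raise ValueError(f"unknown model variant {variant!r}")
    return model
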