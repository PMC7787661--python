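"""Unit and property tests for the planar arm and its muscle mechanics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachopt.biomech import (ArmModel, ArmParams, ArmState, MuscleParams,
                              REF_POSE, activation_derivative, arm_dynamics,
                              default_arm, default_muscles, fiber_length,
                              fiber_velocity, force_length, force_velocity,
                              forward_kinematics, hand_speed, muscle_force,
                              passive_force, simulate)
from reachopt.control import make_plan


class TestForwardKinematics:
    @pytest.mark.parametrize("q,expected", [
        ((0.0, 0.0), (0.63, 0.0)),
        ((math.pi / 2, 0.0), (0.0, 0.63)),
    ])
    def test_collinear_poses(self, arm, q, expected):
        np.testing.assert_allclose(forward_kinematics(np.array(q), arm),
                                   expected, atol=1e-12)

    def test_matches_direct_trigonometry(self):
        arm = ArmParams(lengths=(0.3, 0.3))
        q = np.array([math.pi / 4, math.pi / 2])
        # independent evaluation: link 1 at 45 deg, link 2 at 135 deg
        expected = (0.3 * math.cos(math.pi / 4) + 0.3 * math.cos(3 * math.pi / 4),
                    0.3 * math.sin(math.pi / 4) + 0.3 * math.sin(3 * math.pi / 4))
        np.testing.assert_allclose(forward_kinematics(q, arm), expected,
                                   rtol=1e-12)

    def test_vectorized_over_series(self, arm):
        qs = np.random.default_rng(0).uniform(-1, 2, size=(7, 2))
        batch = forward_kinematics(qs, arm)
        for i, q in enumerate(qs):
            np.testing.assert_allclose(batch[i], forward_kinematics(q, arm))


class TestHandSpeed:
    def test_stationary_arm_has_zero_speed(self, muscle_model):
        plan = make_plan(0.0, 6, 0.2)
        traj = simulate(plan, muscle_model, 0.2)
        np.testing.assert_allclose(traj.speed, 0.0, atol=1e-9)

    def test_jacobian_and_finite_difference_agree(self, muscle_model):
        plan = make_plan(np.linspace(0, 0.6, 6 * 5), 6, 0.2)
        traj = simulate(plan, muscle_model, 0.2)
        fd = hand_speed(traj, method="fd")
        jac = hand_speed(traj, muscle_model.arm, method="jacobian")
        # central differences agree to O(dt) away from the endpoints
        np.testing.assert_allclose(jac[1:-1], fd[1:-1], atol=5e-3)

    def test_single_link_reduction_matches_analytic(self):
        # elbow frozen at 0: speed = |l1 + l2| * |qd1|
        arm = default_arm()
        n = 100
        t = np.linspace(0, 1, n)
        qd1 = 0.7
        q = np.stack([qd1 * t, np.zeros(n)], axis=1)
        qd = np.tile([qd1, 0.0], (n, 1))
        from reachopt.biomech import Trajectory
        hand = forward_kinematics(q, arm)
        traj = Trajectory(t=t, q=q, qd=qd, activations=np.zeros((n, 0)),
                          excitations=np.zeros((n, 0)), hand=hand,
                          speed=np.zeros(n), T=1.0, dt=t[1] - t[0])
        speeds = hand_speed(traj, arm)
        np.testing.assert_allclose(speeds, sum(arm.lengths) * qd1, rtol=1e-12)


class TestForceLength:
    def test_peak_at_optimal_length(self):
        assert force_length(1.0) == 1.0

    def test_one_width_away_is_exp_minus_one(self):
        w = 0.45
        np.testing.assert_allclose(force_length(1.0 + w, width=w), math.exp(-1))
        np.testing.assert_allclose(force_length(1.0 - w, width=w), math.exp(-1))

    def test_flat_ablation_returns_one_everywhere(self):
        for ln in (0.6, 1.0, 1.4):
            assert force_length(ln, const=True) == 1.0

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            force_length(0.0)


class TestForceVelocity:
    def test_isometric_is_one(self):
        assert force_velocity(0.0) == 1.0

    def test_unloaded_shortening_is_zero(self):
        np.testing.assert_allclose(force_velocity(-10.0, vmax=10.0), 0.0,
                                   atol=1e-12)

    def test_eccentric_exceeds_isometric_below_plateau(self):
        fv = force_velocity(5.0, vmax=10.0, ecc_plateau=1.5)
        assert 1.0 < fv <= 1.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-12, 12), st.floats(-12, 12))
    def test_monotone_nondecreasing(self, v1, v2):
        lo, hi = sorted((v1, v2))
        assert force_velocity(lo) <= force_velocity(hi) + 1e-12


class TestMuscleForce:
    def test_full_activation_at_optimum_gives_fmax(self, muscle):
        assert muscle_force(1.0, 1.0, 0.0, muscle) == muscle.fmax

    def test_zero_activation_at_optimum_gives_zero(self, muscle):
        assert muscle_force(0.0, 1.0, 0.0, muscle) == 0.0

    def test_product_matches_independent_evaluation(self, muscle):
        a, ln, vn = 0.5, 1.1, -0.2 * muscle.vmax
        expected = (a * muscle.fmax
                    * math.exp(-(((ln - 1) / muscle.fl_width) ** 2))
                    * (1 + vn / muscle.vmax) / (1 - (vn / muscle.vmax) / 0.25)
                    + muscle.fmax * muscle.passive_coef * (ln - 1) ** 2)
        np.testing.assert_allclose(muscle_force(a, ln, vn, muscle), expected,
                                   rtol=1e-12)

    def test_out_of_range_activation_rejected(self, muscle):
        with pytest.raises(ValueError):
            muscle_force(1.2, 1.0, 0.0, muscle)


class TestActivationDynamics:
    def test_equilibrium(self, muscle):
        assert activation_derivative(0.3, 0.3, muscle) == 0.0

    def test_rising_rate(self, muscle):
        np.testing.assert_allclose(activation_derivative(1.0, 0.0, muscle),
                                   1.0 / muscle.tau_act)

    def test_step_response_matches_closed_form(self, muscle_model):
        # constant full excitation: a(t) = 1 - exp(-t/tau_act)
        plan = make_plan(1.0, 6, 0.2)
        traj = simulate(plan, muscle_model, 0.2, dt=1e-4)
        tau = muscle_model.muscles[0].tau_act
        expected = 1.0 - np.exp(-traj.t / tau)
        np.testing.assert_allclose(traj.activations[:, 0], expected, atol=5e-3)


class TestArmDynamics:
    def test_rest_without_forces_stays_at_rest(self, arm):
        state = ArmState(q=np.array([0.3, 0.9]), qd=np.zeros(2))
        np.testing.assert_allclose(arm_dynamics(state, np.zeros(2), arm), 0.0)

    def test_torque_clipping_at_tau_max(self, arm):
        state = ArmState(q=np.array([0.3, 0.9]), qd=np.zeros(2))
        qdd_req = arm_dynamics(state, np.array([80.0, 0.0]), arm)
        qdd_cap = arm_dynamics(state, np.array([50.0, 0.0]), arm)
        np.testing.assert_allclose(qdd_req, qdd_cap)

    def test_small_oscillation_period_matches_pendulum(self):
        # shrink link 2 to a near-massless stub: single pendulum about the
        # shoulder with I_eff = I1 + m1 d1^2, restoring torque m1 g d1
        arm = ArmParams(lengths=(0.30, 0.01), masses=(2.0, 1e-6),
                        inertias=(0.015, 1e-10), com_offsets=(0.15, 5e-3),
                        damping=0.0, gravity=True,
                        q_lower=(-4.0, -4.0), q_upper=(4.0, 4.0))
        model = ArmModel(arm=arm, muscles=[], mode="torque")
        amp = 0.02
        state = ArmState(q=np.array([-math.pi / 2 + amp, 0.0]), qd=np.zeros(2))
        plan = make_plan(0.0, 2, 2.0, mode="torque")
        traj = simulate(plan, model, 2.0, dt=1e-4, initial_state=state)
        theta = traj.q[:, 0] + math.pi / 2
        # period from successive positive-going zero crossings
        crossings = traj.t[1:][(theta[:-1] < 0) & (theta[1:] >= 0)]
        assert len(crossings) >= 2
        measured = np.diff(crossings).mean()
        I_eff = arm.inertias[0] + arm.masses[0] * arm.com_offsets[0] ** 2
        expected = 2 * math.pi * math.sqrt(
            I_eff / (arm.masses[0] * 9.81 * arm.com_offsets[0]))
        np.testing.assert_allclose(measured, expected, rtol=2e-3)


class TestSimulate:
    def test_zero_excitation_is_stationary(self, muscle_model):
        plan = make_plan(0.0, 6, 0.3)
        traj = simulate(plan, muscle_model, 0.3)
        np.testing.assert_allclose(traj.q - traj.q[0], 0.0, atol=1e-12)

    def test_determinism_bit_identical(self, muscle_model, rng):
        knots = rng.uniform(0, 0.8, size=6 * 7)
        plan = make_plan(knots, 6, 0.4)
        t1 = simulate(plan, muscle_model, 0.4)
        t2 = simulate(plan, muscle_model, 0.4)
        assert np.array_equal(t1.q, t2.q) and np.array_equal(t1.qd, t2.qd)

    def test_step_halving_converges(self, muscle_model, rng):
        knots = rng.uniform(0, 0.6, size=6 * 7)
        plan = make_plan(knots, 6, 0.4)
        h1 = simulate(plan, muscle_model, 0.4, dt=1e-3).hand[-1]
        h2 = simulate(plan, muscle_model, 0.4, dt=5e-4).hand[-1]
        h3 = simulate(plan, muscle_model, 0.4, dt=2.5e-4).hand[-1]
        # first-order scheme: error shrinks ~2x per halving
        assert np.linalg.norm(h2 - h3) < np.linalg.norm(h1 - h2)
        assert np.linalg.norm(h1 - h2) < 2e-3

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_activations_always_clipped(self, seed):
        model = ArmModel(arm=default_arm(), muscles=default_muscles())
        knots = np.random.default_rng(seed).uniform(-3, 3, size=6 * 6)
        traj = simulate(make_plan(knots, 6, 0.3), model, 0.3, dt=2e-3)
        assert traj.activations.min() >= 0.0
        assert traj.activations.max() <= 1.0

    def test_kinetic_energy_decays_with_damping(self):
        arm = default_arm()  # damping > 0, gravity off
        model = ArmModel(arm=arm, muscles=[], mode="torque")
        state = ArmState(q=np.array(REF_POSE), qd=np.array([2.0, -1.5]))
        traj = simulate(make_plan(0.0, 2, 0.5, mode="torque"), model, 0.5,
                        initial_state=state)
        ke = _kinetic_energy(traj, arm)
        assert np.all(np.diff(ke) <= 1e-10)

    def test_muscle_mode_reduces_to_torque_mode(self):
        # constant-scaling muscles with near-instant activation act like
        # torque sources tau = e * fmax * r
        arm = default_arm()
        dt = 1e-3
        e1, e2 = 0.6, 0.3
        fmax, r = 500.0, 0.05
        muscles = [
            MuscleParams("s", fmax=fmax, moment_arms=(r, 0.0), passive_coef=0.0,
                         tau_act=dt, tau_deact=dt),
            MuscleParams("e", fmax=fmax, moment_arms=(0.0, r), passive_coef=0.0,
                         tau_act=dt, tau_deact=dt),
        ]
        m_model = ArmModel(arm=arm, muscles=muscles, fl_const=True,
                           fv_const=True)
        t_model = ArmModel(arm=arm, muscles=[], mode="torque")
        mt = simulate(make_plan(np.array([[e1] * 7, [e2] * 7]), 2, 0.4),
                      m_model, 0.4, dt=dt)
        scale = fmax * r / arm.tau_max
        tt = simulate(make_plan(np.array([[e1 * scale] * 7, [e2 * scale] * 7]),
                                2, 0.4, mode="torque"), t_model, 0.4, dt=dt)
        # activation settles in exactly one step (tau = dt), so the muscle
        # rollout equals the torque rollout delayed by one step
        np.testing.assert_allclose(mt.q[1:], tt.q[:-1], atol=1e-10)
        np.testing.assert_allclose(mt.qd[1:], tt.qd[:-1], atol=1e-10)

    def test_kernel_matches_per_step_reference(self, muscle_model, rng):
        knots = rng.uniform(0, 0.8, size=6 * 7)
        plan = make_plan(knots, 6, 0.4)
        dt = 2e-3
        traj = simulate(plan, muscle_model, 0.4, dt=dt)
        q, qd, act = _reference_rollout(plan, muscle_model, 0.4, dt)
        np.testing.assert_allclose(traj.q, q, rtol=0, atol=1e-12)
        np.testing.assert_allclose(traj.qd, qd, rtol=0, atol=1e-12)
        np.testing.assert_allclose(traj.activations, act, rtol=0, atol=1e-12)


def _kinetic_energy(traj, arm):
    l1, _ = arm.lengths
    m1, m2 = arm.masses
    I1, I2 = arm.inertias
    d1, d2 = arm.com_offsets
    c2 = np.cos(traj.q[:, 1])
    m11 = I1 + I2 + m1 * d1 ** 2 + m2 * (l1 ** 2 + d2 ** 2 + 2 * l1 * d2 * c2)
    m12 = I2 + m2 * (d2 ** 2 + l1 * d2 * c2)
    m22 = I2 + m2 * d2 ** 2
    qd1, qd2 = traj.qd[:, 0], traj.qd[:, 1]
    return 0.5 * (m11 * qd1 ** 2 + 2 * m12 * qd1 * qd2 + m22 * qd2 ** 2)


def _reference_rollout(plan, model, T, dt):
    """Pure-python semi-explicit Euler built from the public step functions."""
    n = int(round(T / dt))
    ts = np.arange(n + 1) * dt
    U = plan.evaluate(ts)
    arm = model.arm
    M = len(model.muscles)
    q = np.zeros((n + 1, 2))
    qd = np.zeros((n + 1, 2))
    act = np.zeros((n + 1, M))
    q[0] = REF_POSE
    for i in range(n):
        torques = np.zeros(2)
        for m, p in enumerate(model.muscles):
            ln = fiber_length(q[i], p, model.q_ref) / p.lopt
            vn = fiber_velocity(qd[i], p) / p.lopt  # optimal lengths / s
            f = muscle_force(act[i, m], ln, vn, p, model.fl_const,
                             model.fv_const)
            torques += np.asarray(p.moment_arms) * f
            e = float(np.clip(U[i, m], 0, 1))
            a_new = act[i, m] + dt * activation_derivative(e, act[i, m], p)
            act[i + 1, m] = np.clip(a_new, 0, 1)
        state = ArmState(q=q[i], qd=qd[i], activations=act[i])
        qdd = arm_dynamics(state, np.clip(torques, -arm.tau_max, arm.tau_max),
                           arm)
        qd[i + 1] = qd[i] + dt * qdd
        q[i + 1] = q[i] + dt * qd[i + 1]
    return q, qd, act
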