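"""Compiled inner loop for forward rollouts.

The semi-explicit Euler integration runs for ~10^3 sequential steps per
candidate plan and several hundred candidates per optimization, so the step
loop is compiled with numba.  The formulas duplicate the public per-step
functions in :mod:`reachopt.biomech`; the two routes are asserted equivalent
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rollout_kernel"]


@njit(cache=False, fastmath=False)
def rollout_kernel(U, q0, qd0, dt,
                   l1, m1, m2, I1, I2, d1, d2,
                   damping, g, tau_max,
                   fmax, lopt, vmax, tau_act, tau_deact, R,
                   q_ref, fl_width, ecc_plateau, passive_coef,
                   ks, ke,
                   fl_const, fv_const, torque_mode):
    """Integrate N = U.shape[0]-1 steps; returns (q, qd, act, fail_step)."""
    n = U.shape[0] - 1
    nm = fmax.shape[0]
    q = np.empty((n + 1, 2))
    qd = np.empty((n + 1, 2))
    act = np.zeros((n + 1, nm))
    q[0, 0] = q0[0]
    q[0, 1] = q0[1]
    qd[0, 0] = qd0[0]
    qd[0, 1] = qd0[1]

    for i in range(n):
        q1 = q[i, 0]
        q2 = q[i, 1]
        qd1 = qd[i, 0]
        qd2 = qd[i, 1]

        tau1 = 0.0
        tau2 = 0.0
        if torque_mode:
            u1 = min(max(U[i, 0], -1.0), 1.0)
            u2 = min(max(U[i, 1], -1.0), 1.0)
            tau1 = u1 * tau_max
            tau2 = u2 * tau_max
        else:
            for m in range(nm):
                a = act[i, m]
                # fiber geometry under constant moment arms
                fl_len = lopt[m] - (R[m, 0] * (q1 - q_ref[0]) + R[m, 1] * (q2 - q_ref[1]))
                ln = fl_len / lopt[m]
                v = -(R[m, 0] * qd1 + R[m, 1] * qd2)  # m/s, shortening < 0
                vn = v / (vmax[m] * lopt[m])  # fraction of vmax

                if fl_const:
                    fl = 1.0
                else:
                    z = (ln - 1.0) / fl_width[m]
                    fl = np.exp(-z * z)
                if fv_const:
                    fv = 1.0
                elif vn < 0.0:
                    fv = (1.0 + vn) / (1.0 - vn / ks)
                    if fv < 0.0:
                        fv = 0.0
                else:
                    fv = 1.0 + (ecc_plateau[m] - 1.0) * vn / (vn + ke)
                fp = 0.0
                if ln > 1.0:
                    fp = passive_coef[m] * (ln - 1.0) * (ln - 1.0)
                force = a * fmax[m] * fl * fv + fmax[m] * fp
                tau1 += R[m, 0] * force
                tau2 += R[m, 1] * force

                # first-order activation dynamics, driven by clipped excitation
                e = min(max(U[i, m], 0.0), 1.0)
                tau = tau_act[m] if e > a else tau_deact[m]
                a_new = a + dt * (e - a) / tau
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > 1.0:
                    a_new = 1.0
                act[i + 1, m] = a_new

        if tau1 > tau_max:
            tau1 = tau_max
        elif tau1 < -tau_max:
            tau1 = -tau_max
        if tau2 > tau_max:
            tau2 = tau_max
        elif tau2 < -tau_max:
            tau2 = -tau_max

        c2 = np.cos(q2)
        s2 = np.sin(q2)
        m11 = I1 + I2 + m1 * d1 * d1 + m2 * (l1 * l1 + d2 * d2 + 2.0 * l1 * d2 * c2)
        m12 = I2 + m2 * (d2 * d2 + l1 * d2 * c2)
        m22 = I2 + m2 * d2 * d2
        det = m11 * m22 - m12 * m12

        h = m2 * l1 * d2 * s2
        cor1 = -h * qd2 * (2.0 * qd1 + qd2)
        cor2 = h * qd1 * qd1
        if g != 0.0:
            g1 = (m1 * d1 + m2 * l1) * g * np.cos(q1) + m2 * d2 * g * np.cos(q1 + q2)
            g2 = m2 * d2 * g * np.cos(q1 + q2)
        else:
            g1 = 0.0
            g2 = 0.0

        rhs1 = tau1 - cor1 - g1 - damping * qd1
        rhs2 = tau2 - cor2 - g2 - damping * qd2
        qdd1 = (m22 * rhs1 - m12 * rhs2) / det
        qdd2 = (m11 * rhs2 - m12 * rhs1) / det

        # semi-explicit: velocity first, then position with the new velocity
        nqd1 = qd1 + dt * qdd1
        nqd2 = qd2 + dt * qdd2
        nq1 = q1 + dt * nqd1
        nq2 = q2 + dt * nqd2
        if not (np.isfinite(nq1) and np.isfinite(nq2)
                and np.isfinite(nqd1) and np.isfinite(nqd2)):
            return q, qd, act, i
        qd[i + 1, 0] = nqd1
        qd[i + 1, 1] = nqd2
        q[i + 1, 0] = nq1
        q[i + 1, 1] = nq2

    return q, qd, act, -1
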