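"""Shared independent oracles for the test suite."""

import numpy as np


def cox_de_boor_basis(plan, x, k=3):
    """All B-spline basis values at x via the Cox-de Boor recursion."""
    from reachopt.control import _knot_vector
    t = _knot_vector(plan.T, plan.knots.shape[1])
    n = plan.knots.shape[1]

    def B(i, d):
        if d == 0:
            # half-open basis intervals, closed at the right edge of the domain
            if t[i] <= x < t[i + 1]:
                return 1.0
            if x == t[-1] and t[i] < t[i + 1] == t[-1]:
                return 1.0
            return 0.0
        left = 0.0 if t[i + d] == t[i] else \
            (x - t[i]) / (t[i + d] - t[i]) * B(i, d - 1)
        right = 0.0 if t[i + d + 1] == t[i + 1] else \
            (t[i + d + 1] - x) / (t[i + d + 1] - t[i + 1]) * B(i + 1, d - 1)
        return left + right

    return np.array([B(j, k) for j in range(n)])
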