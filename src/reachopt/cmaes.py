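"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact (mu/mu_w, lambda)-CMA-ES with cumulative step-size adaptation and
rank-one plus rank-mu covariance updates, following the standard strategy
parameter settings.  It is the stochastic search engine behind trajectory
optimization: each generation samples candidate knot vectors from a Gaussian
whose mean, scale, and covariance adapt to the ranked costs.

Only what the package needs is implemented: ask/tell iteration, best-ever
tracking, and seed-deterministic sampling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CMAES"]


class CMAES:
    """Minimizer state for one CMA-ES run.

    Parameters
    ----------
    x0 : initial mean, shape (n,)
    sigma0 : initial global step size
    popsize : candidates per generation (lambda), >= 2
    seed : seed for the internal generator
    """

    def __init__(self, x0, sigma0: float, popsize: int = 20, seed: int = 0):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.n = self.mean.size
        if popsize < 2:
            raise ValueError("population size must be >= 2")
        if not sigma0 > 0:
            raise ValueError("sigma0 must be > 0")
        self.sigma = float(sigma0)
        self.lam = int(popsize)
        self.rng = np.random.default_rng(seed)

        n, lam = self.n, self.lam
        self.mu = lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights ** 2)

        self.cc = (4.0 + self.mueff / n) / (n + 4.0 + 2.0 * self.mueff / n)
        self.cs = (self.mueff + 2.0) / (n + self.mueff + 5.0)
        self.c1 = 2.0 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1.0 - self.c1,
                       2.0 * (self.mueff - 2.0 + 1.0 / self.mueff)
                       / ((n + 2.0) ** 2 + self.mueff))
        self.damps = (1.0 + 2.0 * max(0.0, np.sqrt((self.mueff - 1.0) / (n + 1.0)) - 1.0)
                      + self.cs)
        self.chi_n = np.sqrt(n) * (1.0 - 1.0 / (4.0 * n) + 1.0 / (21.0 * n ** 2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self._decompose()
        self.generation = 0
        self.best_x: np.ndarray | None = None
        self.best_f = np.inf
        self._pending_z: np.ndarray | None = None

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2.0
        eigvals, eigvecs = np.linalg.eigh(self.C)
        eigvals = np.maximum(eigvals, 1e-20)
        self.B = eigvecs
        self.D = np.sqrt(eigvals)

    def ask(self) -> np.ndarray:
        """Sample a (lambda, n) array of candidate solutions."""
        z = self.rng.standard_normal((self.lam, self.n))
        y = (self.B * self.D) @ z.T  # (n, lam)
        self._pending_y = y.T
        return self.mean + self.sigma * self._pending_y

    def tell(self, X: np.ndarray, f: np.ndarray) -> None:
        """Rank candidates by cost and update mean, paths, covariance, sigma."""
        f = np.asarray(f, dtype=float)
        order = np.argsort(f, kind="stable")
        if f[order[0]] < self.best_f:
            self.best_f = float(f[order[0]])
            self.best_x = np.asarray(X[order[0]], dtype=float).copy()

        y_sel = self._pending_y[order[: self.mu]]  # (mu, n)
        y_w = self.weights @ y_sel
        self.mean = self.mean + self.sigma * y_w

        # conjugate evolution path for step-size control
        c_inv_sqrt_y = self.B @ ((self.B.T @ y_w) / self.D)
        self.ps = ((1.0 - self.cs) * self.ps
                   + np.sqrt(self.cs * (2.0 - self.cs) * self.mueff) * c_inv_sqrt_y)
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1.0 - (1.0 - self.cs) ** (2 * (self.generation + 1)))
                / self.chi_n) < (1.4 + 2.0 / (self.n + 1.0))
        self.pc = ((1.0 - self.cc) * self.pc
                   + hsig * np.sqrt(self.cc * (2.0 - self.cc) * self.mueff) * y_w)

        rank_mu = (y_sel.T * self.weights) @ y_sel
        delta_hsig = (1 - hsig) * self.cc * (2.0 - self.cc)
        self.C = ((1.0 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc) + delta_hsig * self.C)
                  + self.cmu * rank_mu)

        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chi_n - 1.0))
        self.generation += 1
        self._decompose()
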