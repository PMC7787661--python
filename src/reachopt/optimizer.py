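"""Stochastic trajectory optimization of reach plans.

Each optimization run searches the B-spline knot space with CMA-ES, scoring
candidates by forward simulation plus the trajectory cost.  Because the
search is stochastic and the cost landscape has many local optima, repeated
runs from different seeds land on different solutions; the spread of
movement durations across such an ensemble is the model's operational
definition of motor *planning* variability (there is no execution noise
anywhere in the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .biomech import ArmModel, ArmState, REF_POSE, SimulationDiverged, Trajectory, simulate
from .cmaes import CMAES
from .control import (ControlPlan, CostBreakdown, CostConfig, Target,
                      evaluate_cost, make_plan, movement_duration,
                      n_knots_for_horizon)

__all__ = ["OptimizerConfig", "PlanResult", "optimize_reach", "run_ensemble",
           "best_of", "ENSEMBLE_SEED_STRIDE"]

#: Stride between derived per-run seeds inside an ensemble.
ENSEMBLE_SEED_STRIDE = 10007


@dataclass
class OptimizerConfig:
    """CMA-ES budgets and initialization.

    The default is the reduced preset (population 20 x 40 iterations = 800
    rollouts per run); ``standard()`` gives the 500-iteration budget, 12.5x
    more evaluations.
    """

    population: int = 20
    iterations: int = 40
    sigma0: float = 0.2
    init_knot: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not self.sigma0 > 0:
            raise ValueError("sigma0 must be > 0")

    @classmethod
    def reduced(cls, **kw) -> "OptimizerConfig":
        return cls(population=20, iterations=40, **kw)

    @classmethod
    def standard(cls, **kw) -> "OptimizerConfig":
        return cls(population=20, iterations=500, **kw)

    @property
    def n_evaluations(self) -> int:
        return self.population * self.iterations


@dataclass
class PlanResult:
    """Best-ever solution of one optimization run."""

    plan: ControlPlan
    trajectory: Trajectory
    breakdown: CostBreakdown
    md: float | None
    seed: int
    history: np.ndarray  # best-so-far total cost per iteration
    hit: bool  # final miss distance < zeta
    miss: float
    diverged: int = 0  # candidate rollouts that blew up (scored, not fatal)

    @property
    def cost(self) -> float:
        return self.breakdown.total


def optimize_reach(model: ArmModel, target: Target, T: float,
                   cost_cfg: CostConfig, opt_cfg: OptimizerConfig,
                   dt: float = 1e-3,
                   initial_state: ArmState | None = None,
                   interval: float = 0.1) -> PlanResult:
    """Run one CMA-ES trajectory optimization; deterministic given the seed."""
    n_act = model.n_actuators
    n_k = n_knots_for_horizon(T, interval)
    if n_k < 4:
        raise ValueError("horizon too short for a cubic spline plan")
    mode = "torque" if model.mode == "torque" else "muscle"

    if initial_state is None:
        initial_state = ArmState(q=np.array(REF_POSE), qd=np.zeros(2),
                                 activations=np.zeros(len(model.muscles)))

    diverged = 0
    fail_cost = 10.0 * cost_cfg.C

    def objective(x: np.ndarray) -> float:
        nonlocal diverged
        plan = make_plan(x, n_act, T, interval, mode)
        try:
            traj = simulate(plan, model, T, dt, initial_state)
        except SimulationDiverged:
            diverged += 1
            return fail_cost
        return evaluate_cost(traj, target, cost_cfg, model.arm).total

    es = CMAES(x0=np.full(n_act * n_k, opt_cfg.init_knot),
               sigma0=opt_cfg.sigma0, popsize=opt_cfg.population,
               seed=opt_cfg.seed)
    history = np.empty(opt_cfg.iterations)
    for it in range(opt_cfg.iterations):
        X = es.ask()
        f = np.array([objective(x) for x in X])
        es.tell(X, f)
        history[it] = es.best_f

    if es.best_x is None or es.best_f >= fail_cost:
        raise RuntimeError("all candidate rollouts diverged; no usable solution")

    best_plan = make_plan(es.best_x, n_act, T, interval, mode)
    best_traj = simulate(best_plan, model, T, dt, initial_state)
    breakdown = evaluate_cost(best_traj, target, cost_cfg, model.arm)
    miss = float(np.linalg.norm(best_traj.hand[-1] - target.center))
    md = movement_duration(best_traj, target)
    return PlanResult(plan=best_plan, trajectory=best_traj, breakdown=breakdown,
                      md=md, seed=opt_cfg.seed, history=history,
                      hit=miss < cost_cfg.zeta, miss=miss, diverged=diverged)


def run_ensemble(n_runs: int, base_seed: int, model: ArmModel, target: Target,
                 T: float, cost_cfg: CostConfig, opt_cfg: OptimizerConfig,
                 dt: float = 1e-3,
                 initial_state: ArmState | None = None) -> list[PlanResult]:
    """Independent optimization runs with derived seeds; the ensemble's MD
    spread is the model's planning-variability distribution."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results = []
    for i in range(n_runs):
        cfg_i = replace(opt_cfg, seed=base_seed + i * ENSEMBLE_SEED_STRIDE)
        results.append(optimize_reach(model, target, T, cost_cfg, cfg_i,
                                      dt=dt, initial_state=initial_state))
    return results


def best_of(results: list[PlanResult]) -> PlanResult:
    """Lowest-total-cost result; ties broken by the earlier (smaller) seed."""
    if not results:
        raise ValueError("best_of needs a non-empty result list")
    return min(results, key=lambda r: (r.cost, r.seed))
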