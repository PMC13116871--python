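"""Allocation optimization.

Single-period budget split across domains by equalising marginal
Cobb-Douglas gains (a bracketed search on the Lagrange multiplier), and
multi-period policy search over constant-fraction health-spend rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from iwb.core_index import DomainLevels, ElasticityVector, integrated_wellbeing
from iwb.errors import InvalidScenarioError
from iwb.lifecycle_sim import Policy, Scenario, Trajectory, simulate, trajectory_summary

#: Relative tolerance on the budget residual of the static solver.
BUDGET_TOL = 1e-10

_DERIV_STEP = 1e-7


@dataclass(frozen=True)
class Objective:
    """Intertemporal objective for policy search.

    ``terminal_IW`` scores the last period's integrated wellbeing,
    ``mean_IW`` the average over the horizon, and ``discounted_IW`` the
    discounted sum with rate ``rho`` (rho = 0 reduces to the plain sum).
    """

    kind: str = "mean_IW"
    rho: float = 0.0

    _KINDS = ("terminal_IW", "mean_IW", "discounted_IW")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise InvalidScenarioError(
                f"objective.kind: must be one of {self._KINDS}, got {self.kind!r}"
            )
        if self.rho < 0.0:
            raise InvalidScenarioError(f"objective.rho: must be >= 0, got {self.rho!r}")

    def evaluate(self, traj: Trajectory) -> float:
        iw = traj.column("IW")
        if self.kind == "terminal_IW":
            return iw[-1]
        if self.kind == "mean_IW":
            return math.fsum(iw) / len(iw)
        disc = 1.0 / (1.0 + self.rho)
        return math.fsum(v * disc**k for k, v in enumerate(iw))


@dataclass(frozen=True)
class StaticProblem:
    """One-period allocation problem over named domains.

    Each domain carries an increasing concave investment function, a carry-
    over level x, and a decay rate delta; post-spend levels are
    x' = min(1, (1 - delta)*x + I(C)).
    """

    theta: ElasticityVector
    invest_fns: Mapping[str, Callable[[float], float]]
    carryover: Mapping[str, float]
    deltas: Mapping[str, float]

    def level_after(self, domain: str, C: float) -> float:
        base = (1.0 - self.deltas[domain]) * self.carryover[domain]
        return min(1.0, base + self.invest_fns[domain](C))

    def objective(self, alloc: Mapping[str, float]) -> float:
        levels = DomainLevels(
            {d: self.level_after(d, alloc.get(d, 0.0)) for d in self.theta.domains}
        )
        return integrated_wellbeing(levels, self.theta)


def _marginal_gain(problem: StaticProblem, domain: str, C: float) -> float:
    """theta_d * I'(C) / x'(C): the marginal log-objective gain of one more
    unit of spend in the domain; +inf while the level is still zero, zero
    once the level caps at 1."""
    theta_d = problem.theta[domain]
    x_after = problem.level_after(domain, C)
    if x_after >= 1.0:
        return 0.0
    fn = problem.invest_fns[domain]
    h = _DERIV_STEP * max(1.0, C)
    deriv = (fn(C + h) - fn(max(0.0, C - h))) / (h + min(h, C))
    if x_after <= 0.0:
        return math.inf
    return theta_d * deriv / x_after


def _spend_at_multiplier(problem: StaticProblem, domain: str, mu: float, C_max: float) -> float:
    """Invert the decreasing marginal-gain curve: the spend at which the
    domain's marginal gain equals mu, clipped to [0, C_max]."""
    if _marginal_gain(problem, domain, 0.0) <= mu:
        return 0.0
    if _marginal_gain(problem, domain, C_max) >= mu:
        return C_max
    lo, hi = 0.0, C_max
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _marginal_gain(problem, domain, mid) > mu:
            lo = mid
        else:
            hi = mid
        if hi - lo <= BUDGET_TOL * max(1.0, C_max):
            break
    return 0.5 * (lo + hi)


def optimal_static_allocation(R: float, problem: StaticProblem) -> dict[str, float]:
    """Split a budget R across domains to maximise integrated wellbeing.

    Equalises the marginal gain theta_i * I_i'(C_i) / x_i' across interior
    domains via a bracketed bisection on the Lagrange multiplier, spending
    the full budget unless every domain caps at level 1 first. Budget
    residual tolerance is ``BUDGET_TOL`` (relative).

    Raises
    ------
    InvalidScenarioError
        If R <= 0.
    """
    if R <= 0.0:
        raise InvalidScenarioError(f"budget R must be > 0, got {R!r}")
    domains = problem.theta.domains
    if all(problem.level_after(d, 0.0) >= 1.0 for d in domains):
        return {d: 0.0 for d in domains}

    def total_spend(mu: float) -> float:
        return math.fsum(_spend_at_multiplier(problem, d, mu, R) for d in domains)

    # Bracket the multiplier: high mu -> zero spend, low mu -> full budget
    # (or every domain capped, in which case caps are the optimum).
    mu_hi = 1.0
    while total_spend(mu_hi) > 0.0 and mu_hi < 1e18:
        mu_hi *= 4.0
    mu_lo = 1.0
    while total_spend(mu_lo) < R and mu_lo > 1e-18:
        mu_lo /= 4.0
    if total_spend(mu_lo) < R:
        # Budget cannot be exhausted usefully: all domains cap below R.
        return {d: _spend_at_multiplier(problem, d, 0.0, R) for d in domains}
    for _ in range(200):
        mu = math.sqrt(mu_lo * mu_hi)
        s = total_spend(mu)
        if s > R:
            mu_lo = mu
        else:
            mu_hi = mu
        if abs(s - R) <= BUDGET_TOL * max(1.0, R):
            break
    alloc = {d: _spend_at_multiplier(problem, d, mu, R) for d in domains}
    # Normalise the residual onto uncapped domains so the budget binds exactly.
    spent = math.fsum(alloc.values())
    residual = R - spent
    if abs(residual) > 0.0:
        open_domains = [d for d in domains if problem.level_after(d, alloc[d]) < 1.0]
        if open_domains:
            share = residual / len(open_domains)
            for d in open_domains:
                alloc[d] = max(0.0, alloc[d] + share)
    return alloc


def grid_policy_search(
    scenario: Scenario,
    phi_grid: Sequence[float],
    objective: Objective = Objective(),
) -> tuple[float, list[dict]]:
    """Simulate each constant-fraction health-spend policy and return the
    best fraction plus the full objective surface.

    Returns ``(best_phi, table)`` where each table row carries phi, the
    objective value and terminal summary statistics. Ties break toward the
    smaller phi.
    """
    if not phi_grid:
        raise InvalidScenarioError("phi_grid must be non-empty")
    for phi in phi_grid:
        if not 0.0 <= phi <= 1.0:
            raise InvalidScenarioError(f"phi_grid entries must lie in [0, 1], got {phi!r}")
    table: list[dict] = []
    best_phi, best_value = None, -math.inf
    for phi in sorted(phi_grid):
        traj = simulate(scenario, Policy.constant_fraction(phi))
        summ = trajectory_summary(traj)
        value = objective.evaluate(traj)
        table.append(
            {
                "phi": phi,
                "objective": value,
                "terminal_P": traj.records[-1]["P"],
                "terminal_OF": summ.terminal_OF,
                "terminal_F": summ.terminal_F,
                "mean_IW": summ.mean_IW,
            }
        )
        if value > best_value:
            best_phi, best_value = phi, value
    return best_phi, table


def wellbeing_frontier(
    scenario: Scenario, phi_grid: Sequence[float]
) -> list[tuple[float, float, float]]:
    """(terminal F, terminal P, mean IW) for each constant-fraction policy,
    suitable for plotting the cross-domain trade-off surface."""
    _, table = grid_policy_search(scenario, phi_grid)
    return [(row["terminal_F"], row["terminal_P"], row["mean_IW"]) for row in table]


def symmetric_static_problem(
    theta: ElasticityVector, slope: float = 1.0
) -> StaticProblem:
    """Linear-investment, zero-carryover static problem used as the
    closed-form oracle fixture: the optimum is C_i = theta_i * R."""
    return StaticProblem(
        theta=theta,
        invest_fns={d: (lambda C, m=slope: m * C) for d in theta.domains},
        carryover={d: 0.0 for d in theta.domains},
        deltas={d: 0.0 for d in theta.domains},
    )
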